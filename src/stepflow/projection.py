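"""Local map projection for converting GPS longitude/latitude to planar meters.

Step lengths are Euclidean distances in a projected plane, so fixes recorded
as WGS84 degrees must be projected before any geometry is computed.  A local
transverse Mercator centred on the data keeps scale distortion far below GPS
positional error at the ~10 km extent of a tracking study (relative scale
error < 1e-6 within a few kilometres of the central meridian).

The spherical form is used: its inverse is exact in closed form, so
``lonlat -> xy -> lonlat`` round-trips to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (IUGG), meters.
EARTH_RADIUS = 6_371_008.8


@dataclass(frozen=True)
class LocalTransverseMercator:
    """Spherical transverse Mercator centred at (``lon0``, ``lat0``) degrees.

    The projection origin maps to ``(x, y) = (0, 0)``; x grows east, y north.
    """

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS

    def forward(self, lon, lat):
        """Project degrees to planar meters. Accepts scalars or arrays."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        b = np.cos(phi) * np.sin(lam)
        x = self.radius * np.arctanh(b)
        y = self.radius * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
        return x, y

    def inverse(self, x, y):
        """Exact inverse: planar meters back to (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        d = y + np.radians(self.lat0)
        lat = np.degrees(np.arcsin(np.sin(d) / np.cosh(x)))
        lon = self.lon0 + np.degrees(np.arctan2(np.sinh(x), np.cos(d)))
        return lon, lat

    @classmethod
    def for_centroid(cls, lon, lat) -> "LocalTransverseMercator":
        """Projection centred on the centroid of the supplied coordinates."""
        return cls(lon0=float(np.mean(lon)), lat0=float(np.mean(lat)))
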