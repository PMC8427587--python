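"""Run configuration: sampling schedule, filtering thresholds, projection.

All durations are in seconds unless the field name says otherwise.  Defaults
follow the data-collection protocol the pipeline targets: a 5-min GPS
schedule, bursts of at least 50 fixes (about four hours), a three-day
post-capture exclusion window, and a 3-sample (9-min) activity smoothing
window.  The analysis season defaults to 23 April – 8 August, applied as a
month-day window in every year of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


#: Default Movebank-style column names for fix CSV files.
DEFAULT_FIX_COLUMNS = {
    "individual": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "x": "x",
    "y": "y",
}


@dataclass
class RunConfig:
    sampling_interval: float = 300.0
    schedule_tolerance: float = 30.0
    min_burst_fixes: int = 50
    post_capture_exclusion_days: float = 3.0
    smoothing_window: int = 3
    hmm_restarts: int = 5
    rng_seed: int = 0
    season_start: str = "04-23"   # month-day, inclusive
    season_end: str = "08-08"     # month-day, inclusive
    projection_lon0: Optional[float] = None   # None: centre on data centroid
    projection_lat0: Optional[float] = None
    fix_columns: dict = field(default_factory=lambda: dict(DEFAULT_FIX_COLUMNS))

    def __post_init__(self):
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be positive")
        if self.schedule_tolerance < 0:
            raise ConfigError("schedule_tolerance must be non-negative")
        if self.min_burst_fixes < 2:
            raise ConfigError("min_burst_fixes must be >= 2")
        if self.post_capture_exclusion_days < 0:
            raise ConfigError("post_capture_exclusion_days must be >= 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be odd and >= 1")
        for md in (self.season_start, self.season_end):
            _parse_month_day(md)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _parse_month_day(md: str) -> tuple[int, int]:
    try:
        month, day = md.split("-")
        month, day = int(month), int(day)
    except Exception as exc:
        raise ConfigError(f"bad month-day string {md!r}; expected 'MM-DD'") from exc
    if not (1 <= month <= 12 and 1 <= day <= 31):
        raise ConfigError(f"month-day out of range: {md!r}")
    return month, day
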