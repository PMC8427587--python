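"""Burst segmentation and movement-step construction.

A *burst* is an uninterrupted run of fixes on the regular sampling schedule
(default 5 min); a *step* joins two consecutive fixes within a burst.  Step
length S (meters per interval) proxies movement speed; the turning angle is
the change in heading between consecutive steps, signed in (-pi, pi] for the
state model and absolute in [0, pi] as a directionality response.  Steps are
never built across burst boundaries or across removed fixes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import ConfigError, RunConfig

logger = logging.getLogger("stepflow")


def segment_bursts(fixes: pd.DataFrame, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Assign a ``burst_id`` to each fix.

    Consecutive fixes of one individual share a burst while their time gap is
    within ``sampling_interval ± schedule_tolerance``; any other gap starts a
    new burst.  Burst ids are unique per individual (and globally).
    """
    config = config or RunConfig()
    out = fixes.sort_values(["individual_id", "timestamp"], kind="stable").copy()
    gap = out.groupby("individual_id", sort=False)["timestamp"].diff().dt.total_seconds()
    on_schedule = (gap - config.sampling_interval).abs() <= config.schedule_tolerance
    new_burst = ~on_schedule.fillna(False)
    out["burst_id"] = np.cumsum(new_burst.to_numpy().astype(int)) - 1
    return out.reset_index(drop=True)


def filter_bursts(fixes: pd.DataFrame, min_burst_fixes: int = 50) -> pd.DataFrame:
    """Drop all fixes belonging to bursts shorter than ``min_burst_fixes``."""
    sizes = fixes.groupby("burst_id")["timestamp"].transform("size")
    keep = sizes >= min_burst_fixes
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_bursts: removed %d fixes in short bursts", n_removed)
    out = fixes[keep].reset_index(drop=True)
    out.attrs["n_removed_short_burst"] = n_removed
    return out


def remove_post_capture(fixes: pd.DataFrame,
                        capture_dates: Mapping[str, pd.Timestamp],
                        days: float = 3.0) -> pd.DataFrame:
    """Drop fixes within ``days`` after each individual's capture time.

    Tag behaviour immediately after capture is not representative, so the
    first days of data are excluded.  A fix at exactly capture + days is kept.
    """
    missing = set(fixes["individual_id"].unique()) - set(map(str, capture_dates))
    if missing:
        raise ConfigError(f"no capture date for individual(s): {sorted(missing)}")
    cutoff = fixes["individual_id"].map(
        {str(k): pd.Timestamp(v) + pd.Timedelta(days=days)
         for k, v in capture_dates.items()})
    keep = fixes["timestamp"] >= cutoff
    n_removed = int((~keep).sum())
    out = fixes[keep].reset_index(drop=True)
    out.attrs["n_removed_post_capture"] = n_removed
    return out


def wrap_angle(a):
    """Wrap radians into (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)   # maps odd multiples of pi to +pi
    return w


def build_steps(fixes: pd.DataFrame) -> pd.DataFrame:
    """Build one step per consecutive fix pair within each burst.

    Returns a table with columns ``individual_id, burst_id, t_start, t_end,
    x0, y0, S, heading, alpha_signed, alpha_abs``.  The first step of a burst
    has no previous heading, hence missing turning angles.
    """
    f = fixes.sort_values(["individual_id", "burst_id", "timestamp"], kind="stable")
    g = f.groupby("burst_id", sort=False)
    dx = g["x"].diff()
    dy = g["y"].diff()
    has_step = dx.notna()

    steps = pd.DataFrame({
        "individual_id": f["individual_id"][has_step],
        "burst_id": f["burst_id"][has_step],
        "t_end": f["timestamp"][has_step],
        "S": np.hypot(dx[has_step], dy[has_step]),
        "heading": np.arctan2(dy[has_step], dx[has_step]),
    })
    steps["t_start"] = g["timestamp"].shift(1)[has_step]
    steps["x0"] = g["x"].shift(1)[has_step]
    steps["y0"] = g["y"].shift(1)[has_step]

    steps = steps.reset_index(drop=True)
    prev_heading = steps.groupby("burst_id", sort=False)["heading"].shift(1)
    alpha = wrap_angle(steps["heading"] - prev_heading)
    alpha[prev_heading.isna()] = np.nan
    steps["alpha_signed"] = alpha
    steps["alpha_abs"] = np.abs(alpha)
    order = ["individual_id", "burst_id", "t_start", "t_end", "x0", "y0",
             "S", "heading", "alpha_signed", "alpha_abs"]
    return steps[order]
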