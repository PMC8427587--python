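"""Fuse activity and movement-state labels; exclude false-movement steps.

Crossing the accelerometer label (active/resting) with the decoded movement
state (stationary/transient) yields four step classes.  A *resting-transient*
step — the tag says the bird was at rest while the GPS geometry implies a
large displacement — is interpreted as GPS positional error ("false
movement") and excluded from analysis.  Excluded steps are kept in the table
with ``included=False`` for auditability rather than deleted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .activity import UNKNOWN
from .config import _parse_month_day

logger = logging.getLogger("stepflow")

FUSED_CLASSES = ["active-transient", "active-stationary",
                 "resting-stationary", "resting-transient"]


class PipelineOrderError(RuntimeError):
    """A stage ran before the labels it consumes were produced."""


@dataclass
class FilterReport:
    n_input: int
    n_per_class: dict
    n_excluded_resting_transient: int
    n_excluded_unknown_activity: int
    n_included: int

    def to_json(self, path) -> None:
        d = asdict(self)
        d["pct_excluded"] = round(
            100.0 * (self.n_input - self.n_included) / max(self.n_input, 1), 3)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def fuse_and_filter(steps: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Assign the four-way fused class and mark resting-transient excluded.

    Steps with unknown activity (outside accelerometer coverage) are also
    marked excluded; they are counted separately in the report.
    """
    for col in ("activity", "movestate"):
        if col not in steps.columns:
            raise PipelineOrderError(
                f"fuse_and_filter needs column {col!r}; run the labelling stages first")
    out = steps.copy()
    known = out["activity"] != UNKNOWN
    out["fused"] = np.where(
        known, out["activity"].astype(str) + "-" + out["movestate"].astype(str),
        UNKNOWN)
    out["included"] = known & (out["fused"] != "resting-transient")
    report = FilterReport(
        n_input=len(out),
        n_per_class={c: int((out["fused"] == c).sum()) for c in FUSED_CLASSES},
        n_excluded_resting_transient=int((out["fused"] == "resting-transient").sum()),
        n_excluded_unknown_activity=int((~known).sum()),
        n_included=int(out["included"].sum()),
    )
    assert report.n_included + report.n_excluded_resting_transient \
        + report.n_excluded_unknown_activity == report.n_input
    logger.info("fuse_and_filter: %s", report.n_per_class)
    return out, report


def crop_season(steps: pd.DataFrame, start: str = "04-23",
                end: str = "08-08") -> pd.DataFrame:
    """Keep steps whose start month-day falls in [start, end], any year.

    Month-day comparison (rather than day-of-year) keeps the window stable
    across leap years.
    """
    m0, d0 = _parse_month_day(start)
    m1, d1 = _parse_month_day(end)
    md = steps["t_start"].dt.month * 100 + steps["t_start"].dt.day
    keep = (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)
    out = steps[keep].reset_index(drop=True)
    out.attrs["n_removed_season"] = int((~keep).sum())
    return out


def recompute_lag(steps: pd.DataFrame) -> pd.DataFrame:
    """Attach the previous step length ``S_prev`` to every included step.

    Within a burst, ``S_prev`` is the length of the immediately preceding
    included step when that step is temporally adjacent (its end is this
    step's start).  Burst origins and steps following an excluded step get
    the overall mean S of included steps; ``s_prev_imputed`` marks them.
    """
    out = steps.copy()
    inc = out["included"] if "included" in out.columns else pd.Series(True, index=out.index)
    mean_s = out.loc[inc, "S"].mean()
    out["S_prev"] = np.nan
    out["s_prev_imputed"] = False

    sub = out[inc].sort_values(["burst_id", "t_start"], kind="stable")
    g = sub.groupby("burst_id", sort=False)
    prev_s = g["S"].shift(1)
    prev_end = g["t_end"].shift(1)
    adjacent = (sub["t_start"] - prev_end).dt.total_seconds().abs() <= 1.0
    use_prev = prev_s.notna() & adjacent
    s_prev = np.where(use_prev, prev_s, mean_s)
    out.loc[sub.index, "S_prev"] = s_prev
    out.loc[sub.index, "s_prev_imputed"] = ~use_prev.to_numpy()
    frac = float(out.loc[inc, "s_prev_imputed"].mean()) if inc.any() else np.nan
    out.attrs["s_prev_imputed_fraction"] = frac
    logger.info("recompute_lag: %.2f%% of S_prev imputed with the overall mean",
                100 * frac if frac == frac else float("nan"))
    return out
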