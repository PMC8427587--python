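"""Active/resting classification from tri-axial accelerometer bursts.

Physical activity is summarised per 10-s burst as dynamic body acceleration
(DBA): the per-axis static (gravitational) component is the burst mean, the
dynamic component is the residual, and DBA is the mean over samples of the
summed absolute dynamic components (the ODBA convention).  The resulting
3-min series is smoothed with a short moving window and split into active and
resting phases by a per-individual two-class variance-minimising threshold
(Otsu's criterion applied to the raw values).  The threshold is data- and
individual-specific and entirely deterministic.

Steps are labelled *active* only when both endpoints fall inside an active
phase; mixed steps count as resting, which is conservative when the goal is
to catch false movement during rest.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import RunConfig

logger = logging.getLogger("stepflow")

ACTIVE, RESTING, UNKNOWN = "active", "resting", "unknown"


def compute_dba(acc: pd.DataFrame) -> pd.DataFrame:
    """Reduce each accelerometer burst to one DBA value at the burst midpoint.

    DBA is invariant to any constant per-axis offset (gravity, sensor bias);
    empty bursts are skipped.
    """
    acc = acc[acc[["ax", "ay", "az"]].notna().all(axis=1)]
    keys = ["individual_id", "burst_start"]
    g = acc.groupby(keys, sort=True)
    static = g[["ax", "ay", "az"]].transform("mean")
    pointwise = (acc[["ax", "ay", "az"]] - static).abs().sum(axis=1)
    agg = pd.DataFrame({"dba": pointwise, "t_offset": acc["t_offset"]},
                       index=acc.index).groupby(
        [acc["individual_id"], acc["burst_start"]], sort=True).agg(
        dba=("dba", "mean"), span=("t_offset", "max"))
    out = agg.reset_index()
    out["t"] = out["burst_start"] + pd.to_timedelta(out.pop("span") / 2.0, unit="s")
    return out[["individual_id", "t", "dba"]].sort_values(
        ["individual_id", "t"], kind="stable").reset_index(drop=True)


def smooth_activity(values: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Centered moving mean of DBA within each individual's series.

    Edges use the available points (the window shrinks), so the output length
    equals the input length and a window of 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    out = values.copy()
    out["dba_smooth"] = (
        out.groupby("individual_id", sort=False)["dba"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return out


def otsu_threshold(values: np.ndarray) -> Optional[float]:
    """Two-class threshold minimising within-class variance (Otsu, exact).

    Works directly on the sorted sample rather than a histogram: every split
    between consecutive distinct values is scored and the best boundary is
    returned as the midpoint of the straddling pair.  Returns None when the
    series is degenerate (fewer than two distinct values).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        return None
    csum = np.cumsum(v)
    csum2 = np.cumsum(v * v)
    k = np.arange(1, n)                       # lower class = v[:k]
    lo_ss = csum2[k - 1] - csum[k - 1] ** 2 / k
    hi_n = n - k
    hi_sum = csum[-1] - csum[k - 1]
    hi_ss = (csum2[-1] - csum2[k - 1]) - hi_sum ** 2 / hi_n
    valid = v[k] > v[k - 1]                   # only split between distinct values
    score = np.where(valid, lo_ss + hi_ss, np.inf)
    best = int(np.argmin(score))
    return float(0.5 * (v[best] + v[best + 1]))


class ActivityThresholdSegmenter(BaseEstimator):
    """Per-individual unsupervised active/resting segmentation of DBA series.

    Parameters
    ----------
    window : int
        Width (samples) of the centered smoothing window; 3 samples of a
        3-min series spans 9 minutes.
    min_samples : int
        Minimum series length per individual required to estimate a
        threshold; shorter (or constant) series yield a single resting phase.

    Attributes
    ----------
    thresholds_ : dict
        Estimated DBA threshold per individual (None when degenerate).
    phases_ : DataFrame
        Alternating phases with columns
        ``individual_id, state, t_start, t_end``.
    """

    def __init__(self, window: int = 3, min_samples: int = 20):
        self.window = window
        self.min_samples = min_samples

    def fit(self, values: pd.DataFrame, y=None):
        smoothed = (values if "dba_smooth" in values.columns
                    else smooth_activity(values, self.window))
        self.thresholds_ = {}
        phases = []
        for ind, grp in smoothed.groupby("individual_id", sort=True):
            grp = grp.sort_values("t")
            x = grp["dba_smooth"].to_numpy()
            t = grp["t"].to_numpy()
            thr = (otsu_threshold(x) if len(x) >= self.min_samples else None)
            self.thresholds_[ind] = thr
            if thr is None:
                logger.warning("degenerate DBA series for %s: single resting phase", ind)
                phases.append((ind, RESTING, t[0], t[-1]))
                continue
            active = x > thr
            # phase boundaries at midpoints between adjacent samples
            change = np.flatnonzero(active[1:] != active[:-1])
            bounds = [t[0]] + [t[i] + (t[i + 1] - t[i]) / 2 for i in change] + [t[-1]]
            states = np.concatenate(([active[0]], active[change + 1]))
            for s, t0, t1 in zip(states, bounds[:-1], bounds[1:]):
                phases.append((ind, ACTIVE if s else RESTING, t0, t1))
        self.phases_ = pd.DataFrame(
            phases, columns=["individual_id", "state", "t_start", "t_end"])
        return self

    def predict(self, times: pd.DataFrame) -> np.ndarray:
        """State at each (individual_id, t) row: active/resting/unknown."""
        out = np.full(len(times), UNKNOWN, dtype=object)
        for ind, grp in times.groupby("individual_id", sort=False):
            ph = self.phases_[self.phases_["individual_id"] == ind]
            if ph.empty:
                continue
            starts = ph["t_start"].to_numpy()
            ends = ph["t_end"].to_numpy()
            states = ph["state"].to_numpy()
            t = grp["t"].to_numpy()
            idx = np.searchsorted(starts, t, side="right") - 1
            ok = (idx >= 0) & (t <= ends[np.clip(idx, 0, len(ends) - 1)])
            lab = np.where(ok, states[np.clip(idx, 0, len(states) - 1)], UNKNOWN)
            out[times.index.get_indexer(grp.index)] = lab
        return out


def classify_phases(values: pd.DataFrame,
                    config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Functional wrapper: smoothed series in, alternating phase table out."""
    config = config or RunConfig()
    seg = ActivityThresholdSegmenter(window=config.smoothing_window)
    return seg.fit(values).phases_


def label_step_activity(steps: pd.DataFrame, phases: pd.DataFrame) -> pd.DataFrame:
    """Attach ``activity`` to each step from the phase table.

    A step is active iff both its start and end time fall inside active
    phases (half-open ``[t_start, t_end)``); anything mixed is resting.
    Steps outside accelerometer coverage get ``unknown`` and are excluded
    downstream (the count is logged).
    """
    out = steps.copy()
    start_state = _phase_state_at(phases, out["individual_id"], out["t_start"])
    end_state = _phase_state_at(phases, out["individual_id"], out["t_end"])
    activity = np.where((start_state == ACTIVE) & (end_state == ACTIVE),
                        ACTIVE, RESTING).astype(object)
    unknown = (start_state == UNKNOWN) | (end_state == UNKNOWN)
    activity[unknown] = UNKNOWN
    n_unknown = int(unknown.sum())
    if n_unknown:
        logger.info("label_step_activity: %d steps outside ACC coverage", n_unknown)
    out["activity"] = activity
    return out


def _phase_state_at(phases: pd.DataFrame, individuals: pd.Series,
                    times: pd.Series) -> np.ndarray:
    state = np.full(len(times), UNKNOWN, dtype=object)
    t_all = times.to_numpy()
    pos = np.arange(len(times))
    for ind, ph in phases.groupby("individual_id", sort=False):
        sel = (individuals == ind).to_numpy()
        if not sel.any():
            continue
        starts = ph["t_start"].to_numpy()
        ends = ph["t_end"].to_numpy()
        labels = ph["state"].to_numpy()
        t = t_all[sel]
        idx = np.searchsorted(starts, t, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        # half-open [start, end); the final phase end is closed so the last
        # sample time remains covered
        inside = (idx >= 0) & ((t < ends[idx_c]) |
                               ((idx_c == len(starts) - 1) & (t <= ends[idx_c])))
        state[pos[sel]] = np.where(inside, labels[idx_c], UNKNOWN)
    return state
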