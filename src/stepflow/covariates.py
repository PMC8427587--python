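"""Environmental and temporal covariates attached at each step's start.

Covariates are extracted at the *beginning* of a step — the conditions that
prompted the movement.  All spatial layers are 25-m rasters sharing one
working CRS; lookup is containing-cell with a half-open cell convention so
results are bit-reproducible.  Land cover uses nine classes: two clear-cut
age classes, cultivated land, forest bog, open bog, and four forest
composition classes (mixed, unknown, pine-dominated, spruce-dominated).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CovariateGrid

logger = logging.getLogger("stepflow")

LAND_COVER_CODES = {
    1: "clearcut<=5y",
    2: "clearcut>5y",
    3: "cultivated",
    4: "forest-bog",
    5: "open-bog",
    6: "mixed-forest",
    7: "unknown-forest",
    8: "pine-forest",
    9: "spruce-forest",
}
LAND_COVER_LABELS = list(LAND_COVER_CODES.values())
#: Reference level for regression contrasts: recent clear-cuts.
LAND_COVER_REFERENCE = "clearcut<=5y"

#: Continuous covariates entering the collinearity screen and the models.
CONTINUOUS_COVARIATES = ["dbh", "tree_height", "n_visible_turbines",
                         "shadow_hours", "dist_access_road"]

DOMINANCE_PCT = 75.0     # a species at >=75% basal area dominates the stand
CLEARCUT_MAX_AGE = 20.0  # older clear-cuts have regrown into forest


def classify_forest(pine_pct, spruce_pct, inventory_present=True):
    """Forest composition class from inventory percentages (vectorised).

    Pine or spruce at >= 75% dominates; otherwise the stand is mixed forest,
    or unknown forest where no inventory data exists.
    """
    pine = np.asarray(pine_pct, dtype=float)
    spruce = np.asarray(spruce_pct, dtype=float)
    present = np.asarray(inventory_present, dtype=bool)
    if np.any(present & (pine + spruce > 100.0 + 1e-9)):
        raise ValueError("pine_pct + spruce_pct exceeds 100")
    out = np.where(~present, "unknown-forest",
                   np.where(pine >= DOMINANCE_PCT, "pine-forest",
                            np.where(spruce >= DOMINANCE_PCT, "spruce-forest",
                                     "mixed-forest")))
    return out if out.ndim else out[()]


def classify_clearcut(age_years):
    """Clear-cut age class, or None where the cut is old enough to be forest."""
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise ValueError("clear-cut age must be >= 0")
    out = np.where(age <= 5.0, "clearcut<=5y",
                   np.where(age <= CLEARCUT_MAX_AGE, "clearcut>5y", "none"))
    out = np.where(out == "none", None, out)
    return out if out.ndim else out[()]


def derive_land_cover(base: CovariateGrid, pine_pct: CovariateGrid,
                      spruce_pct: CovariateGrid, clearcut_age: CovariateGrid,
                      inventory: CovariateGrid) -> CovariateGrid:
    """Build the 9-class land-cover grid from its ingredient layers.

    ``base`` codes: 0 forest, 3 cultivated, 4 forest bog, 5 open bog.
    Forest cells are refined into clear-cut age classes (where a clear-cut
    younger than 20 years is recorded) or composition classes.
    """
    code = np.full(base.values.shape, np.nan)
    b = base.values
    for c in (3, 4, 5):
        code[b == c] = c
    forest = b == 0
    age = clearcut_age.values
    cut = forest & np.isfinite(age) & (age >= 0) & (age <= CLEARCUT_MAX_AGE)
    code[cut & (age <= 5.0)] = 1
    code[cut & (age > 5.0)] = 2
    stand = forest & ~cut
    present = inventory.values > 0
    pine, spruce = pine_pct.values, spruce_pct.values
    code[stand & ~present] = 7
    code[stand & present & (pine >= DOMINANCE_PCT)] = 8
    code[stand & present & (pine < DOMINANCE_PCT) & (spruce >= DOMINANCE_PCT)] = 9
    code[stand & present & (pine < DOMINANCE_PCT) & (spruce < DOMINANCE_PCT)] = 6
    return CovariateGrid(layer_name="land_cover", x0=base.x0, y0=base.y0,
                         cell_size=base.cell_size, values=code,
                         nodata=base.nodata, categories=dict(LAND_COVER_CODES))


def extract_at_step_start(steps: pd.DataFrame,
                          grids: dict[str, CovariateGrid]) -> pd.DataFrame:
    """Containing-cell lookup of every layer at each step's start point.

    Layers named in ``LAND_COVER_CODES``-coded grids (key ``land_cover``) are
    decoded to labels.  Steps hitting nodata or falling outside any extent
    get ``covariates_ok=False`` and are excluded from the regressions.
    """
    ref = next(iter(grids.values()))
    for name, g in grids.items():
        if (g.cell_size != ref.cell_size):
            raise ValueError(f"grid {name!r} cell size differs from {ref.layer_name!r}")
    out = steps.copy()
    x = out["x0"].to_numpy()
    y = out["y0"].to_numpy()
    ok = np.ones(len(out), dtype=bool)
    for name, g in grids.items():
        vals = g.value_at(x, y)
        ok &= np.isfinite(vals)
        if name == "land_cover":
            lab = np.full(len(out), "", dtype=object)
            fin = np.isfinite(vals)
            lab[fin] = [LAND_COVER_CODES.get(int(v), "") for v in vals[fin]]
            out[name] = lab
        else:
            out[name] = vals
    out["covariates_ok"] = ok
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("extract_at_step_start: %d steps with nodata/outside extent", n_bad)
    return out


def temporal_covariates(steps: pd.DataFrame) -> pd.DataFrame:
    """Attach decimal UTC hour of day and Julian day (1 Jan = 1)."""
    out = steps.copy()
    t = out["t_start"].dt
    out["daytime"] = t.hour + t.minute / 60.0 + t.second / 3600.0
    out["julian_day"] = t.dayofyear
    return out


def collinearity_screen(table: pd.DataFrame, columns=None,
                        threshold: float = 0.6) -> pd.DataFrame:
    """Pairwise Pearson correlations of continuous covariates.

    Pairs with |r| strictly greater than the threshold are flagged; nothing
    is dropped automatically — the modeller decides which member to keep.
    Zero-variance columns are excluded with a warning.
    """
    cols = [c for c in (columns or CONTINUOUS_COVARIATES) if c in table.columns]
    usable = []
    for c in cols:
        if table[c].std() == 0 or table[c].isna().all():
            logger.warning("collinearity_screen: %r has zero variance; excluded", c)
        else:
            usable.append(c)
    rows = []
    corr = table[usable].corr(method="pearson")
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            r = float(corr.loc[a, b])
            rows.append({"var_a": a, "var_b": b, "r": r,
                         "flagged": abs(r) > threshold})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "flagged"])
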