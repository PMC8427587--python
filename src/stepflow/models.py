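"""Movement speed and directionality regressions.

Two Gamma/log-link penalized regressions are fitted to the filtered step
table:

* **speed**: step length S (meters per 5-min interval), with land-cover
  contrasts (reference: recent clear-cuts), shrinkage smooths of the five
  continuous habitat/turbine covariates capped at 4 df, a cyclic-by-cubic
  tensor smooth of time of day and day of year (5 and 4 df caps), the
  previous step length as a linear covariate to absorb lag-1 autocorrelation,
  and a per-individual random intercept;
* **angle**: absolute turning angle (0..pi), same structure but without the
  lag covariate — turning angles show no residual autocorrelation.

Flexibility caps are enforced through the basis dimension: a smooth with
``k`` basis functions has at most ``k - 1`` effective degrees of freedom
after centering, so ``k = cap + 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .covariates import CONTINUOUS_COVARIATES, LAND_COVER_REFERENCE
from .gam import (FactorTerm, GammaGAM, LinearTerm, RandomInterceptTerm,
                  SmoothTerm, TensorSmoothTerm)
from .hmm import MIN_STEP

logger = logging.getLogger("stepflow")

#: Minimum absolute turning angle (radians): the Gamma support excludes 0.
MIN_ANGLE = 1e-3

SMOOTH_DF_CAP = 4       # habitat/turbine smooths and the seasonal margin
DIEL_DF_CAP = 5         # cyclic time-of-day margin


def speed_model_terms(with_lag: bool = True, smooth_covariates=None) -> list:
    smooth_covariates = (CONTINUOUS_COVARIATES if smooth_covariates is None
                         else smooth_covariates)
    terms = [FactorTerm("land_cover", reference=LAND_COVER_REFERENCE)]
    if with_lag:
        terms.append(LinearTerm("S_prev"))
    terms += [SmoothTerm(c, k=SMOOTH_DF_CAP + 1, shrinkage=True)
              for c in smooth_covariates]
    terms.append(TensorSmoothTerm("daytime", "julian_day",
                                  k1=DIEL_DF_CAP + 1, k2=SMOOTH_DF_CAP + 1,
                                  cyclic1=True, period1=24.0, shrinkage2=True))
    terms.append(RandomInterceptTerm("individual_id"))
    return terms


@dataclass
class FitResult:
    """Fitted model plus the summary tables the analysis reports."""

    model: GammaGAM
    response: str
    coef_table: pd.DataFrame
    smooth_table: pd.DataFrame
    random_intercept_variance: float
    n_obs: int
    acf1_before: Optional[float] = None
    acf1_after: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Gamma/log GAMM for {self.response} (n = {self.n_obs})", ""]
        lines.append(f"{'Predictor':<32}{'Estimate':>10}{'SE':>9}{'p':>9}")
        for _, r in self.coef_table.iterrows():
            lines.append(f"{r['term']:<32}{r['estimate']:>10.3f}"
                         f"{r['se']:>9.3f}{_fmt_p(r['p']):>9}")
        lines.append("")
        lines.append(f"{'Smooth term':<32}{'Edf':>10}{'p':>9}")
        for _, r in self.smooth_table.iterrows():
            lines.append(f"{r['term']:<32}{r['edf']:>10.2f}{_fmt_p(r['p']):>9}")
        lines.append("")
        lines.append(f"Random intercept variance: {self.random_intercept_variance:.4f}")
        if self.acf1_before is not None:
            lines.append(f"Lag-1 residual ACF without previous-step covariate: "
                         f"{self.acf1_before:.3f}")
        if self.acf1_after is not None:
            lines.append(f"Lag-1 residual ACF of final model: {self.acf1_after:.3f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "response": self.response,
            "n_obs": self.n_obs,
            "coefficients": self.coef_table.to_dict(orient="records"),
            "smooths": self.smooth_table.to_dict(orient="records"),
            "random_intercept_variance": self.random_intercept_variance,
            "acf1_before": self.acf1_before,
            "acf1_after": self.acf1_after,
            "edf_total": self.model.edf_,
            "scale": self.model.phi_,
            "notes": self.notes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _fmt_p(p) -> str:
    return "<.001" if p < 1e-3 else f"{p:.3f}"


def _analysis_rows(steps: pd.DataFrame) -> pd.DataFrame:
    keep = steps["included"] if "included" in steps.columns else pd.Series(
        True, index=steps.index)
    if "covariates_ok" in steps.columns:
        keep = keep & steps["covariates_ok"]
    return steps[keep]


def lag1_autocorrelation(residuals: np.ndarray, steps: pd.DataFrame) -> Optional[float]:
    """Pearson correlation of residual pairs on temporally adjacent steps.

    Pairs are formed only within a burst where the earlier step's end equals
    the later step's start; returns None with fewer than two pairs.
    """
    res = pd.Series(np.asarray(residuals, dtype=float), index=steps.index)
    sub = steps.sort_values(["burst_id", "t_start"], kind="stable")
    g = sub.groupby("burst_id", sort=False)
    prev_end = g["t_end"].shift(1)
    prev_idx = pd.Series(sub.index, index=sub.index).groupby(
        sub["burst_id"], sort=False).shift(1)
    adjacent = (sub["t_start"] - prev_end).dt.total_seconds().abs() <= 1.0
    ok = adjacent & prev_idx.notna()
    if ok.sum() < 2:
        return None
    a = res.loc[sub.index[ok]].to_numpy()
    b = res.loc[prev_idx[ok].astype(sub.index.dtype)].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def residual_acf(fit: FitResult | GammaGAM, steps: pd.DataFrame) -> Optional[float]:
    model = fit.model if isinstance(fit, FitResult) else fit
    return lag1_autocorrelation(model.residuals("deviance"), steps)


def _fit(steps: pd.DataFrame, response: np.ndarray, terms, response_name: str,
         gam_kwargs) -> GammaGAM:
    model = GammaGAM(terms=terms, **gam_kwargs)
    model.fit(steps, response)
    logger.info("%s model: edf %.1f, scale %.3f", response_name, model.edf_,
                model.phi_)
    return model


def fit_speed_model(steps: pd.DataFrame, *, check_lag_baseline: bool = True,
                    smooth_covariates=None, **gam_kwargs) -> FitResult:
    """Fit the movement-speed regression on included, covariate-complete steps.

    When ``check_lag_baseline`` is set, a model without the previous-step
    covariate is fitted first so the lag-1 residual autocorrelation can be
    reported before and after its inclusion.
    """
    df = _analysis_rows(steps).reset_index(drop=True)
    y = np.maximum(df["S"].to_numpy(dtype=float), MIN_STEP)
    acf_before = None
    if check_lag_baseline:
        base = _fit(df, y, speed_model_terms(with_lag=False,
                                             smooth_covariates=smooth_covariates),
                    "speed (no lag)", gam_kwargs)
        acf_before = lag1_autocorrelation(base.residuals("deviance"), df)
    model = _fit(df, y, speed_model_terms(with_lag=True,
                                          smooth_covariates=smooth_covariates),
                 "speed", gam_kwargs)
    acf_after = lag1_autocorrelation(model.residuals("deviance"), df)
    rev = model.random_intercept_variance()
    return FitResult(
        model=model, response="step length S (m / 5 min)",
        coef_table=model.coefficient_table(),
        smooth_table=model.smooth_table(),
        random_intercept_variance=rev.get("re(individual_id)", np.nan),
        n_obs=len(df), acf1_before=acf_before, acf1_after=acf_after,
    )


def fit_angle_model(steps: pd.DataFrame, *, smooth_covariates=None,
                    **gam_kwargs) -> FitResult:
    """Fit the directionality regression on absolute turning angles.

    Steps without a turning angle (burst origins) are dropped; zero angles
    are clamped to ``MIN_ANGLE`` to stay inside the Gamma support.
    """
    df = _analysis_rows(steps)
    has_alpha = df["alpha_abs"].notna()
    n_dropped = int((~has_alpha).sum())
    if n_dropped:
        logger.info("fit_angle_model: dropped %d steps without turning angle",
                    n_dropped)
    df = df[has_alpha].reset_index(drop=True)
    y = np.maximum(df["alpha_abs"].to_numpy(dtype=float), MIN_ANGLE)
    n_clamped = int((df["alpha_abs"] < MIN_ANGLE).sum())
    model = _fit(df, y, speed_model_terms(with_lag=False,
                                          smooth_covariates=smooth_covariates),
                 "angle", gam_kwargs)
    rev = model.random_intercept_variance()
    return FitResult(
        model=model, response="absolute turning angle (rad)",
        coef_table=model.coefficient_table(),
        smooth_table=model.smooth_table(),
        random_intercept_variance=rev.get("re(individual_id)", np.nan),
        n_obs=len(df),
        acf1_after=lag1_autocorrelation(model.residuals("deviance"), df),
        notes={"n_angle_missing_dropped": n_dropped,
               "n_angle_clamped": n_clamped},
    )


def predict_effects(fit: FitResult, term: str, grid=None, n_grid: int = 100,
                    training_data: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Response-scale effect of one covariate with all others held at their mean.

    ``term`` is a covariate column name ("land_cover" walks the classes).
    Factors other than the target sit at the reference level and the random
    intercept at zero, so curves are population-level.  Requires the analysis
    table used for fitting (to take covariate means and observed ranges).
    """
    model = fit.model
    if training_data is None:
        raise ValueError("training_data (the analysis table) is required")
    df = _analysis_rows(training_data)
    base = {}
    for t in model.terms:
        if isinstance(t, (SmoothTerm, LinearTerm)):
            base[t.col] = float(df[t.col].mean())
        elif isinstance(t, TensorSmoothTerm):
            base[t.col1] = float(df[t.col1].mean())
            base[t.col2] = float(df[t.col2].mean())
        elif isinstance(t, FactorTerm):
            base[t.col] = t.reference
        elif isinstance(t, RandomInterceptTerm):
            base[t.col] = "__population__"

    if term == "land_cover":
        fac = next(t for t in model.terms if isinstance(t, FactorTerm))
        values = fac.levels_
    else:
        lo, hi = df[term].min(), df[term].max()
        values = np.asarray(grid if grid is not None
                            else np.linspace(lo, hi, n_grid), dtype=float)
        out_of_range = (values < lo) | (values > hi)
        if out_of_range.any():
            logger.warning("predict_effects: %d grid points outside the "
                           "observed range of %r", int(out_of_range.sum()), term)
    rows = pd.DataFrame([dict(base, **{term: v}) for v in values])
    est, se = model.predict(rows, se=True, include_random=False)
    return pd.DataFrame({"term": term, "value": values, "estimate": est,
                         "se": se})
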