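"""Penalized Gamma regression with smooth terms (a small GAM engine).

The model is a generalized additive mixed model with a Gamma response and a
log link:

    log E[y_i] = beta_0 + factor contrasts + linear terms
                 + f_1(x_1i) + ... + te(x_a, x_b) + b_{ind(i)}

Smooths are penalized B-splines (:mod:`stepflow.basis`); the per-individual
intercepts ``b`` enter as a ridge-penalized dummy block, which is the
penalized-regression formulation of an i.i.d. Gaussian random effect.  All
smoothing parameters (one per penalty, including the random-effect ridge)
are chosen by minimising generalized cross-validation,

    GCV(lambda) = n D(lambda) / (n - gamma * edf(lambda))^2,

with the customary inflation ``gamma = 1.4`` guarding against the mild
undersmoothing of plain GCV.  For the Gamma log link the IRLS weights are
identically 1, so the penalized IRLS inner loop reuses a single Cholesky
factor of ``X'X + S(lambda)`` per candidate lambda, and the outer search is
cheap coordinate-wise Brent minimisation.

Standard errors come from the Bayesian posterior covariance
``(X'X + S)^{-1} phi`` with the scale ``phi`` estimated from Pearson
residuals.  P-values for smooth terms are a Wald-type approximation on the
term's coefficient block and are intentionally rough.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .basis import (BSplineBasis, CyclicBSplineBasis, center_constraint,
                    row_kronecker)


class GamError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------

class LinearTerm:
    """A single untransformed covariate column."""

    penalized = False

    def __init__(self, col: str):
        self.col = col
        self.name = col

    def build(self, df: pd.DataFrame):
        return df[self.col].to_numpy(dtype=float)[:, None], []

    def design(self, df: pd.DataFrame):
        return df[self.col].to_numpy(dtype=float)[:, None]


class FactorTerm:
    """Treatment-coded categorical covariate with an explicit reference."""

    penalized = False

    def __init__(self, col: str, reference: str):
        self.col = col
        self.reference = reference
        self.name = col

    def build(self, df: pd.DataFrame):
        vals = df[self.col].astype(str)
        levels = sorted(set(vals))
        ref = self.reference
        if ref not in levels:
            ref = vals.value_counts().idxmax()
            import logging
            logging.getLogger("stepflow").warning(
                "reference level %r absent from %r; using modal level %r",
                self.reference, self.col, ref)
        self.levels_ = [ref] + [l for l in levels if l != ref]
        return self.design(df), []

    def design(self, df: pd.DataFrame):
        vals = df[self.col].astype(str)
        unseen = set(vals) - set(self.levels_)
        if unseen:
            raise GamError(f"unseen level(s) {sorted(unseen)} in {self.col!r}")
        X = np.zeros((len(df), len(self.levels_) - 1))
        for j, lev in enumerate(self.levels_[1:]):
            X[:, j] = (vals == lev).to_numpy(dtype=float)
        return X

    @property
    def contrast_names(self):
        return [f"{self.col}[{l}]" for l in self.levels_[1:]]


class SmoothTerm:
    """Penalized B-spline smooth of one covariate, sum-to-zero centred.

    ``k`` caps the flexibility: after centering, the term has ``k - 1``
    coefficients so its effective degrees of freedom cannot exceed
    ``k - 1``.  With ``shrinkage=True`` the penalty is eigen-modified so the
    smoothing parameter can remove the term entirely.
    """

    penalized = True

    def __init__(self, col: str, k: int = 5, shrinkage: bool = True):
        self.col = col
        self.k = k
        self.shrinkage = shrinkage
        self.name = f"s({col})"

    def _make_basis(self):
        return BSplineBasis(k=self.k, shrinkage=self.shrinkage)

    def build(self, df: pd.DataFrame):
        x = df[self.col].to_numpy(dtype=float)
        self.basis_ = self._make_basis().set_range(x)
        X = self.basis_.design(x)
        self.Z_ = center_constraint(X)
        S = self.Z_.T @ self.basis_.penalty() @ self.Z_
        return X @ self.Z_, [S]

    def design(self, df: pd.DataFrame):
        return self.basis_.design(df[self.col].to_numpy(dtype=float)) @ self.Z_


class CyclicSmoothTerm(SmoothTerm):
    """Cyclic penalized smooth; the fitted curve wraps at ``period``."""

    def __init__(self, col: str, k: int = 6, period: float = 24.0):
        super().__init__(col, k=k, shrinkage=False)
        self.period = period
        self.name = f"s({col},cyclic)"

    def _make_basis(self):
        return CyclicBSplineBasis(k=self.k, period=self.period)


class TensorSmoothTerm:
    """Tensor-product smooth of two covariates with one penalty per margin.

    The default pairs a cyclic margin (time of day) with a shrinkage cubic
    margin (day of year).  A single sum-to-zero constraint is imposed on the
    full tensor block.
    """

    penalized = True

    def __init__(self, col1: str, col2: str, *, k1: int = 6, k2: int = 5,
                 cyclic1: bool = True, period1: float = 24.0,
                 shrinkage2: bool = True):
        self.col1, self.col2 = col1, col2
        self.k1, self.k2 = k1, k2
        self.cyclic1 = cyclic1
        self.period1 = period1
        self.shrinkage2 = shrinkage2
        self.name = f"te({col1},{col2})"

    def build(self, df: pd.DataFrame):
        x1 = df[self.col1].to_numpy(dtype=float)
        x2 = df[self.col2].to_numpy(dtype=float)
        self.b1_ = (CyclicBSplineBasis(k=self.k1, period=self.period1)
                    if self.cyclic1 else
                    BSplineBasis(k=self.k1, shrinkage=False)).set_range(x1)
        self.b2_ = BSplineBasis(k=self.k2, shrinkage=self.shrinkage2).set_range(x2)
        X = row_kronecker(self.b1_.design(x1), self.b2_.design(x2))
        self.Z_ = center_constraint(X)
        S1 = np.kron(self.b1_.penalty(), np.eye(self.k2))
        S2 = np.kron(np.eye(self.k1), self.b2_.penalty())
        return X @ self.Z_, [self.Z_.T @ S1 @ self.Z_, self.Z_.T @ S2 @ self.Z_]

    def design(self, df: pd.DataFrame):
        X = row_kronecker(self.b1_.design(df[self.col1].to_numpy(dtype=float)),
                          self.b2_.design(df[self.col2].to_numpy(dtype=float)))
        return X @ self.Z_


class RandomInterceptTerm:
    """I.i.d. Gaussian random intercept as a ridge-penalized dummy block."""

    penalized = True

    def __init__(self, col: str):
        self.col = col
        self.name = f"re({col})"

    def build(self, df: pd.DataFrame):
        vals = df[self.col].astype(str)
        self.levels_ = sorted(set(vals))
        return self.design(df), [np.eye(len(self.levels_))]

    def design(self, df: pd.DataFrame):
        vals = df[self.col].astype(str)
        X = np.zeros((len(df), len(self.levels_)))
        index = {l: j for j, l in enumerate(self.levels_)}
        for i, v in enumerate(vals):
            j = index.get(v)
            if j is not None:       # unseen individuals predict at 0
                X[i, j] = 1.0
        return X


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

def gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


class GammaGAM(BaseEstimator):
    """Penalized Gamma GAM with log link (see module docstring).

    Parameters
    ----------
    terms : list
        Term objects (:class:`LinearTerm`, :class:`FactorTerm`,
        :class:`SmoothTerm`, :class:`CyclicSmoothTerm`,
        :class:`TensorSmoothTerm`, :class:`RandomInterceptTerm`).  An
        intercept is always included.
    gcv_gamma : float
        Effective-df inflation in the GCV denominator.
    n_sweeps : int
        Coordinate-descent sweeps over the smoothing parameters.
    rho_bounds : tuple
        Search bounds for each log smoothing parameter.
    """

    def __init__(self, terms=None, gcv_gamma: float = 1.4, n_sweeps: int = 3,
                 rho_bounds: tuple = (-10.0, 22.0), pirls_tol: float = 1e-8,
                 max_pirls: int = 50):
        self.terms = terms
        self.gcv_gamma = gcv_gamma
        self.n_sweeps = n_sweeps
        self.rho_bounds = rho_bounds
        self.pirls_tol = pirls_tol
        self.max_pirls = max_pirls

    # -- design assembly ----------------------------------------------------

    def _assemble(self, df: pd.DataFrame):
        blocks = [np.ones((len(df), 1))]
        self.slices_ = {"intercept": slice(0, 1)}
        self.penalties_ = []      # (term_name, slice, matrix)
        col = 1
        for term in self.terms:
            X, pens = term.build(df)
            sl = slice(col, col + X.shape[1])
            self.slices_[term.name] = sl
            blocks.append(X)
            for S in pens:
                self.penalties_.append((term.name, sl, S))
            col += X.shape[1]
        return np.hstack(blocks)

    def _design(self, df: pd.DataFrame, exclude=()):
        blocks = [np.ones((len(df), 1))]
        for term in self.terms:
            X = term.design(df)
            if term.name in exclude:
                X = np.zeros_like(X)
            blocks.append(X)
        return np.hstack(blocks)

    def _penalty_total(self, rho):
        p = self.n_coef_
        S = np.zeros((p, p))
        for (name, sl, Sj), r in zip(self.penalties_, rho):
            S[sl, sl] += np.exp(r) * Sj
        return S

    # -- fitting ------------------------------------------------------------

    def _pirls(self, XtX, S, X, y, eta0):
        """Penalized IRLS at fixed smoothing; returns beta, eta, deviance.

        Step halving and convergence monitor the *penalized* deviance
        ``D(beta) + beta' S beta`` — the quantity the update actually
        minimises — so the iteration is monotone.
        """
        A = XtX + S
        A[np.diag_indices_from(A)] += 1e-10
        try:
            chol = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as exc:
            raise GamError("penalized normal equations not positive definite "
                           "(rank deficiency?)") from exc
        eta = eta0.copy()
        mu = np.exp(eta)
        beta = None
        pdev = np.inf
        for _ in range(self.max_pirls):
            z = eta + (y - mu) / mu
            beta_new = cho_solve(chol, X.T @ z)
            if beta is None:
                beta = beta_new
                eta = X @ beta
                pdev = gamma_deviance(y, np.exp(eta)) + float(beta @ S @ beta)
                mu = np.exp(eta)
                continue
            step = 1.0
            while True:                       # step halving on divergence
                beta_try = beta + step * (beta_new - beta)
                eta_try = X @ beta_try
                pdev_try = (gamma_deviance(y, np.exp(eta_try))
                            + float(beta_try @ S @ beta_try))
                if np.isfinite(pdev_try) and (pdev_try <= pdev + 1e-12
                                              or step < 1e-4):
                    break
                step /= 2.0
            converged = abs(pdev - pdev_try) < self.pirls_tol * (abs(pdev_try) + 0.1)
            beta, eta, pdev = beta_try, eta_try, pdev_try
            mu = np.exp(eta)
            if converged:
                break
        dev = gamma_deviance(y, mu)
        return beta, eta, dev, chol

    def fit(self, df: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise GamError("Gamma response must be strictly positive")
        X = self._assemble(df)
        self.n_coef_ = X.shape[1]
        n = len(y)
        XtX = X.T @ X
        eta0 = np.full(n, np.log(y.mean()))
        state = {"eta": eta0}

        def gcv(rho):
            S = self._penalty_total(rho)
            try:
                beta, eta, dev, chol = self._pirls(XtX, S, X, y, state["eta"])
            except GamError:
                return np.inf
            state["eta"] = eta                   # warm start
            edf = float(np.trace(cho_solve(chol, XtX)))
            denom = n - self.gcv_gamma * edf
            if denom <= 1.0:
                return np.inf
            return n * dev / denom ** 2

        n_pen = len(self.penalties_)
        rho = np.zeros(n_pen)
        if n_pen:
            for _ in range(self.n_sweeps):
                for j in range(n_pen):
                    def obj(r, j=j):
                        trial = rho.copy()
                        trial[j] = r
                        return gcv(trial)
                    res = optimize.minimize_scalar(
                        obj, bounds=self.rho_bounds, method="bounded",
                        options={"xatol": 5e-2})
                    rho[j] = res.x
        self.rho_ = rho

        S = self._penalty_total(rho)
        beta, eta, dev, chol = self._pirls(XtX, S, X, y, state["eta"])
        mu = np.exp(eta)
        F = cho_solve(chol, XtX)                 # edf matrix
        self.coef_ = beta
        self.edf_ = float(np.trace(F))
        self.edf_by_term_ = {
            name: float(np.trace(F[sl, sl]))
            for name, sl in self.slices_.items()}
        self.deviance_ = dev
        self.phi_ = float(np.sum(((y - mu) / mu) ** 2) / max(n - self.edf_, 1.0))
        self.cov_ = cho_solve(chol, np.eye(self.n_coef_)) * self.phi_
        self.fitted_ = mu
        self.eta_ = eta
        self.n_obs_ = n
        self.y_ = y
        # GCV at the optimum, for reporting
        self.gcv_ = n * dev / (n - self.gcv_gamma * self.edf_) ** 2
        return self

    # -- inference helpers --------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        """Estimates, SEs and Wald p-values for the unpenalized coefficients."""
        check_is_fitted(self, "coef_")
        rows = [("Intercept", 0)]
        for term in self.terms:
            if isinstance(term, FactorTerm):
                sl = self.slices_[term.name]
                rows += list(zip(term.contrast_names, range(sl.start, sl.stop)))
            elif isinstance(term, LinearTerm):
                rows.append((term.name, self.slices_[term.name].start))
        out = []
        for label, j in rows:
            est = self.coef_[j]
            se = float(np.sqrt(self.cov_[j, j]))
            z = est / se if se > 0 else np.nan
            out.append({"term": label, "estimate": est, "se": se,
                        "p": 2 * stats.norm.sf(abs(z))})
        return pd.DataFrame(out)

    def smooth_table(self) -> pd.DataFrame:
        """Effective df and approximate Wald p-value per penalized term."""
        check_is_fitted(self, "coef_")
        seen = []
        out = []
        for name, sl, _ in self.penalties_:
            if name in seen:
                continue
            seen.append(name)
            b = self.coef_[sl]
            V = self.cov_[sl, sl]
            edf = self.edf_by_term_[name]
            try:
                T = float(b @ np.linalg.pinv(V, rcond=1e-8) @ b)
                p = float(stats.chi2.sf(T, max(edf, 1.0)))
            except np.linalg.LinAlgError:
                p = np.nan
            out.append({"term": name, "edf": edf, "p": p})
        return pd.DataFrame(out)

    def random_intercept_variance(self) -> dict:
        """Estimated variance of each random-intercept block (phi / lambda)."""
        check_is_fitted(self, "coef_")
        out = {}
        for (name, sl, S), r in zip(self.penalties_, self.rho_):
            term = next(t for t in self.terms if t.name == name)
            if isinstance(term, RandomInterceptTerm):
                out[name] = self.phi_ / np.exp(r)
        return out

    # -- prediction ---------------------------------------------------------

    def predict(self, df: pd.DataFrame, *, se: bool = False,
                include_random: bool = True, response_scale: bool = True):
        """Predict at new rows; random intercepts can be zeroed.

        With ``se=True`` returns ``(prediction, se)`` where the SE band is on
        the same scale as the prediction (delta method on the response
        scale).
        """
        check_is_fitted(self, "coef_")
        exclude = () if include_random else tuple(
            t.name for t in self.terms if isinstance(t, RandomInterceptTerm))
        X = self._design(df, exclude=exclude)
        eta = X @ self.coef_
        pred = np.exp(eta) if response_scale else eta
        if not se:
            return pred
        var = np.einsum("ij,jk,ik->i", X, self.cov_, X)
        se_eta = np.sqrt(np.maximum(var, 0))
        return pred, (pred * se_eta if response_scale else se_eta)

    def residuals(self, kind: str = "deviance") -> np.ndarray:
        check_is_fitted(self, "coef_")
        y, mu = self.y_, self.fitted_
        if kind == "pearson":
            return (y - mu) / mu
        d = 2.0 * (-np.log(y / mu) + (y - mu) / mu)
        return np.sign(y - mu) * np.sqrt(np.maximum(d, 0))
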