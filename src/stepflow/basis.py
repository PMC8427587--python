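"""Penalized spline bases for the smooth regression terms.

All 1-D smooths are penalized B-splines (P-splines): a modest cubic B-spline
basis on equally spaced knots with a second-order difference penalty on the
coefficients.  Three variants are provided:

* an ordinary smooth (difference penalty; constant + linear null space),
* a *shrinkage* smooth, whose penalty is eigen-modified so that a large
  enough smoothing parameter shrinks the whole term — null space included —
  to zero, letting the data remove a covariate entirely,
* a *cyclic* smooth whose basis functions wrap around a period, so the
  fitted curve and its derivatives match at the two ends.

Tensor-product smooths combine two marginal bases by a row-wise Kronecker
product with one penalty (and one smoothing parameter) per margin.

Bases are built from the training data and frozen (knot range, centering
constraint), so design matrices for new data are reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

#: Null-space eigenvalues of a shrinkage penalty are replaced by this
#: multiple of the smallest strictly positive eigenvalue.
SHRINKAGE_EPS = 0.1


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _cyclic_difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.zeros((k, k))
    for i in range(k):
        d[i, i] = 1.0
        d[i, (i + 1) % k] = -2.0
        d[i, (i + 2) % k] = 1.0
    return d.T @ d


def shrinkage_modify(S: np.ndarray, eps: float = SHRINKAGE_EPS) -> np.ndarray:
    """Replace a penalty's zero eigenvalues by a small positive value.

    The returned matrix is full rank, so lambda -> inf shrinks every
    component of the term to zero while leaving moderately penalized fits
    essentially unchanged (the added eigenvalues are a small fraction of the
    smallest curvature eigenvalue).
    """
    d, u = np.linalg.eigh(S)
    tol = max(d.max(), 0) * 1e-9
    pos = d > tol
    if pos.all() or not pos.any():
        return S
    d = np.where(pos, d, eps * d[pos].min())
    return (u * d) @ u.T


class BSplineBasis:
    """Cubic B-spline basis on equally spaced knots over the data range.

    Parameters
    ----------
    k : int
        Number of basis functions (before any centering constraint).
    shrinkage : bool
        Use the shrinkage-modified difference penalty.
    """

    cyclic = False

    def __init__(self, k: int = 5, shrinkage: bool = False, degree: int = 3):
        if k < degree + 1:
            raise ValueError(f"need at least {degree + 1} basis functions")
        self.k = k
        self.shrinkage = shrinkage
        self.degree = degree

    def set_range(self, x: np.ndarray) -> "BSplineBasis":
        x = np.asarray(x, dtype=float)
        self.lo_, self.hi_ = float(np.min(x)), float(np.max(x))
        if self.hi_ <= self.lo_:
            self.hi_ = self.lo_ + 1.0
        d = self.degree
        n_interior = self.k - d - 1
        interior = np.linspace(self.lo_, self.hi_, n_interior + 2)[1:-1]
        self.knots_ = np.concatenate([[self.lo_] * (d + 1), interior,
                                      [self.hi_] * (d + 1)])
        return self

    def design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo_, self.hi_)
        return BSpline.design_matrix(x, self.knots_, self.degree,
                                     extrapolate=False).toarray()

    def penalty(self) -> np.ndarray:
        S = _difference_penalty(self.k)
        return shrinkage_modify(S) if self.shrinkage else S


class CyclicBSplineBasis:
    """Cubic B-spline basis wrapped on ``[0, period)``.

    Basis functions are translates on a uniform knot grid with columns
    identified modulo ``k``, so every basis function (hence any fitted
    curve) is exactly periodic.
    """

    cyclic = True

    def __init__(self, k: int = 6, period: float = 24.0, degree: int = 3):
        if k < degree + 1:
            raise ValueError(f"need at least {degree + 1} basis functions")
        self.k = k
        self.period = period
        self.degree = degree

    def set_range(self, x: np.ndarray) -> "CyclicBSplineBasis":
        d = self.degree
        h = self.period / self.k
        self.knots_ = np.arange(-d, self.k + d + 1) * h
        return self

    def design(self, x) -> np.ndarray:
        x = np.mod(np.asarray(x, dtype=float), self.period)
        full = BSpline.design_matrix(x, self.knots_, self.degree,
                                     extrapolate=False).toarray()
        out = np.zeros((full.shape[0], self.k))
        for j in range(full.shape[1]):
            out[:, j % self.k] += full[:, j]
        return out

    def penalty(self) -> np.ndarray:
        return _cyclic_difference_penalty(self.k)


def center_constraint(X: np.ndarray) -> np.ndarray:
    """Null-space transform Z imposing the sum-to-zero constraint 1'XZb = 0.

    Returns Z of shape (k, k-1); using columns ``X @ Z`` makes the smooth
    orthogonal to the intercept.
    """
    c = X.sum(axis=0, keepdims=True)
    z = null_space(c)
    if z.shape[1] != X.shape[1] - 1:       # constant column edge case
        raise ValueError("degenerate centering constraint")
    return z


def row_kronecker(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product for tensor smooths."""
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)
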