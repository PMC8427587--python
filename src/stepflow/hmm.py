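"""Two-state hidden Markov model for step length and turning angle.

States are *stationary* (short, undirected steps) and *transient* (long,
directed steps).  Emissions are a gamma distribution for step length,
parameterised by mean and standard deviation, and a von Mises distribution
for the signed turning angle with mean fixed at zero (standard practice for
step-and-turn models; only the concentration differs between states).  Each
burst is an independent realisation of the chain, restarting from the
stationary distribution of the transition matrix.

Fitting is direct numerical maximum likelihood on an unconstrained working
scale (log means/sds/concentrations, logit self-transition probabilities)
with multiple jittered restarts; decoding uses the Viterbi algorithm.  The
forward recursion and Viterbi run in log space, vectorised across bursts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

STATIONARY, TRANSIENT = 0, 1
STATE_NAMES = np.array(["stationary", "transient"])

#: Step lengths below this (meters) are clamped before fitting: the gamma
#: density has support (0, inf) and 1 cm is well below GPS error.
MIN_STEP = 0.01


class HmmError(RuntimeError):
    """Raised when no restart of the likelihood optimisation converges."""


@dataclass
class HmmParams:
    """Parameters of the 2-state step/turn HMM (index 0 = stationary)."""

    mu: np.ndarray          # gamma mean per state, meters
    sigma: np.ndarray       # gamma sd per state, meters
    kappa: np.ndarray       # von Mises concentration per state
    tpm: np.ndarray         # 2x2 transition matrix, rows sum to 1
    delta: np.ndarray = None  # initial distribution; default: stationary dist

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.tpm = np.asarray(self.tpm, dtype=float)
        if np.any(self.mu <= 0) or np.any(self.sigma <= 0):
            raise ValueError("gamma mean and sd must be positive")
        if np.any(self.kappa < 0):
            raise ValueError("von Mises concentration must be >= 0")
        if not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.delta is None:
            self.delta = stationary_distribution(self.tpm)
        else:
            self.delta = np.asarray(self.delta, dtype=float)

    def to_dict(self) -> dict:
        return {
            "states": list(STATE_NAMES),
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "kappa": self.kappa.tolist(), "tpm": self.tpm.tolist(),
            "delta": self.delta.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        return cls(mu=d["mu"], sigma=d["sigma"], kappa=d["kappa"],
                   tpm=d["tpm"], delta=d.get("delta"))


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2x2 stochastic matrix."""
    a, b = tpm[0, 1], tpm[1, 0]
    if a + b <= 0:
        return np.array([0.5, 0.5])
    return np.array([b, a]) / (a + b)


# ---------------------------------------------------------------------------
# Emission densities and burst packing
# ---------------------------------------------------------------------------

def _gamma_logpdf(s, mu, sigma):
    shape = (mu / sigma) ** 2
    scale = sigma ** 2 / mu
    return stats.gamma.logpdf(s, a=shape, scale=scale)


def _vonmises_logpdf(alpha, kappa):
    # mean 0; log I0 computed via the exponentially scaled Bessel function
    return kappa * np.cos(alpha) - (np.log(2 * np.pi)
                                    + np.log(special.i0e(kappa)) + kappa)


def pack_bursts(steps: pd.DataFrame):
    """Pad per-burst step sequences into rectangular arrays.

    Returns ``(S, alpha, mask, order)`` with shapes (n_bursts, T_max); mask
    is True where a real step exists; ``order`` gives the row index in
    ``steps`` of every packed position so decoded states can be unpacked.
    """
    s_list, a_list, i_list = [], [], []
    idx = np.arange(len(steps))
    for _, grp_idx in steps.groupby("burst_id", sort=False).indices.items():
        s_list.append(steps["S"].to_numpy()[grp_idx])
        a_list.append(steps["alpha_signed"].to_numpy()[grp_idx])
        i_list.append(idx[grp_idx])
    n, tmax = len(s_list), max(len(s) for s in s_list)
    S = np.full((n, tmax), np.nan)
    alpha = np.full((n, tmax), np.nan)
    mask = np.zeros((n, tmax), dtype=bool)
    order = np.full((n, tmax), -1, dtype=int)
    for i, (s, a, ii) in enumerate(zip(s_list, a_list, i_list)):
        S[i, :len(s)] = s
        alpha[i, :len(a)] = a
        mask[i, :len(s)] = True
        order[i, :len(ii)] = ii
    return S, alpha, mask, order


def _log_emissions(params: HmmParams, S, alpha, mask):
    """Per-step log density under each state; shape (n, T, 2).

    Steps with a missing turning angle (burst origins) contribute the step
    length density only.
    """
    s = np.where(mask, np.maximum(S, MIN_STEP), 1.0)
    logb = np.stack(
        [_gamma_logpdf(s, params.mu[k], params.sigma[k]) for k in (0, 1)],
        axis=-1)
    has_alpha = mask & np.isfinite(alpha)
    a = np.where(has_alpha, alpha, 0.0)
    for k in (0, 1):
        logb[..., k] += np.where(has_alpha, _vonmises_logpdf(a, params.kappa[k]), 0.0)
    logb[~mask] = 0.0
    return logb


# ---------------------------------------------------------------------------
# Forward algorithm and Viterbi
# ---------------------------------------------------------------------------

def forward_loglik(params: HmmParams, steps: pd.DataFrame = None, *,
                   packed=None) -> float:
    """Forward-algorithm log likelihood, summed over independent bursts.

    Scaled linear-space recursion: per-step emission densities are
    normalised by their cross-state maximum (re-added to the total), and the
    forward vector is renormalised at every step, so arbitrarily long bursts
    neither under- nor overflow.
    """
    S, alpha, mask, _ = packed if packed is not None else pack_bursts(steps)
    logb = _log_emissions(params, S, alpha, mask)
    bmax = logb.max(axis=2)                          # (n, T)
    B = np.exp(logb - bmax[:, :, None])
    total = float((bmax * mask).sum())
    a = params.delta[None, :] * B[:, 0, :]           # (n, 2)
    c = a.sum(axis=1)
    total += float(np.log(c).sum())
    a /= c[:, None]
    tpm = params.tpm
    for t in range(1, S.shape[1]):
        live = mask[:, t]
        a_new = (a @ tpm) * B[:, t, :]
        c = a_new.sum(axis=1)
        safe_c = np.where(live, c, 1.0)
        total += float(np.log(safe_c[live]).sum())
        a = np.where(live[:, None], a_new / safe_c[:, None], a)
    return total


def viterbi(params: HmmParams, steps: pd.DataFrame) -> np.ndarray:
    """Most probable state sequence per burst; ties break toward stationary.

    Returns an integer array aligned with ``steps`` rows (0 = stationary,
    1 = transient).
    """
    S, alpha, mask, order = pack_bursts(steps)
    n, tmax = S.shape
    logb = _log_emissions(params, S, alpha, mask)
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.delta)
        log_tpm = np.log(params.tpm)
    score = log_delta[None, :] + logb[:, 0, :]
    back = np.zeros((n, tmax, 2), dtype=int)
    for t in range(1, tmax):
        cand = score[:, :, None] + log_tpm[None, :, :]       # (n, from, to)
        # argmax over 'from', preferring stationary (index 0) on exact ties
        best_from = np.where(cand[:, 0, :] >= cand[:, 1, :], 0, 1)
        best_score = np.take_along_axis(cand, best_from[:, None, :], axis=1)[:, 0, :]
        new_score = best_score + logb[:, t, :]
        back[:, t, :] = best_from
        score = np.where(mask[:, t, None], new_score, score)

    states = np.full((n, tmax), -1, dtype=int)
    lengths = mask.sum(axis=1)
    last = np.where(score[:, 0] >= score[:, 1], 0, 1)
    for i in range(n):
        L = lengths[i]
        states[i, L - 1] = last[i]
        for t in range(L - 1, 0, -1):
            states[i, t - 1] = back[i, t, states[i, t]]
    out = np.empty(len(steps), dtype=int)
    out[order[mask]] = states[mask]
    return out


def brute_force_loglik(params: HmmParams, steps: pd.DataFrame) -> float:
    """Exhaustive path-sum likelihood; exponential cost, oracle use only."""
    total = 0.0
    for _, grp in steps.groupby("burst_id", sort=False):
        S, alpha, mask, _ = pack_bursts(grp.reset_index(drop=True))
        logb = _log_emissions(params, S, alpha, mask)[0]
        T = int(mask.sum())
        terms = []
        for bits in range(2 ** T):
            path = [(bits >> t) & 1 for t in range(T)]
            lp = np.log(params.delta[path[0]]) + logb[0, path[0]]
            for t in range(1, T):
                lp += np.log(params.tpm[path[t - 1], path[t]]) + logb[t, path[t]]
            terms.append(lp)
        total += special.logsumexp(terms)
    return float(total)


def brute_force_viterbi(params: HmmParams, steps: pd.DataFrame) -> np.ndarray:
    """Exhaustive most-probable path (ties toward the all-smaller-state path)."""
    out = []
    for _, grp in steps.groupby("burst_id", sort=False):
        S, alpha, mask, _ = pack_bursts(grp.reset_index(drop=True))
        logb = _log_emissions(params, S, alpha, mask)[0]
        T = int(mask.sum())
        best_lp, best_path = -np.inf, None
        for bits in range(2 ** T):
            path = [(bits >> t) & 1 for t in range(T)]
            lp = np.log(params.delta[path[0]]) + logb[0, path[0]]
            for t in range(1, T):
                lp += np.log(params.tpm[path[t - 1], path[t]]) + logb[t, path[t]]
            if lp > best_lp or (lp == best_lp and path < best_path):
                best_lp, best_path = lp, path
        out.extend(best_path)
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

def _theta_to_params(theta: np.ndarray) -> HmmParams:
    mu = np.exp(theta[0:2])
    sigma = np.exp(theta[2:4])
    kappa = np.exp(theta[4:6])
    stay = special.expit(theta[6:8])
    tpm = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
    return HmmParams(mu=mu, sigma=sigma, kappa=kappa, tpm=tpm)


def _params_to_theta(p: HmmParams) -> np.ndarray:
    return np.concatenate([np.log(p.mu), np.log(p.sigma), np.log(p.kappa),
                           special.logit(np.diag(p.tpm))])


class StepHMM(BaseEstimator):
    """Sklearn-style estimator for the 2-state gamma / von Mises step HMM.

    Parameters
    ----------
    n_restarts : int
        Random restarts of the likelihood optimisation; the first start uses
        deterministic moment estimates from a median split of step length,
        further starts jitter it log-normally (sd ``jitter_sd``).
    random_state : int or None
        Seed for the restart jitter.
    tol : float
        Convergence tolerance on the log likelihood.

    Attributes
    ----------
    params_ : HmmParams
        Fitted parameters, relabelled so the transient state has the larger
        gamma mean.
    log_likelihood_ : float
    converged_ : bool
    n_restarts_used_ : int
    """

    def __init__(self, n_restarts: int = 5, random_state=None,
                 jitter_sd: float = 0.3, tol: float = 1e-6, maxiter: int = 500):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.jitter_sd = jitter_sd
        self.tol = tol
        self.maxiter = maxiter

    def _initial_theta(self) -> np.ndarray:
        return _params_to_theta(self.init_params_)

    def fit(self, steps: pd.DataFrame, y=None):
        if len(steps) < 2:
            raise ValueError("need at least 2 steps to fit the HMM")
        packed = pack_bursts(steps)
        s = np.maximum(steps["S"].to_numpy(dtype=float), MIN_STEP)

        med = np.median(s)
        lo, hi = s[s <= med], s[s > med]
        self.init_params_ = HmmParams(
            mu=[lo.mean(), hi.mean()],
            sigma=[max(lo.std(), 0.1 * lo.mean()), max(hi.std(), 0.1 * hi.mean())],
            kappa=[0.5, 2.0],
            tpm=[[0.9, 0.1], [0.1, 0.9]],
        )
        theta0 = self._initial_theta()
        rng = np.random.default_rng(self.random_state)

        def nll(theta):
            with np.errstate(over="ignore", invalid="ignore"):
                val = -forward_loglik(_theta_to_params(theta), packed=packed)
            return val if np.isfinite(val) else 1e12

        best = None
        n_used = 0
        for r in range(max(1, self.n_restarts)):
            start = theta0 if r == 0 else theta0 + rng.normal(0, self.jitter_sd,
                                                              theta0.shape)
            res = optimize.minimize(nll, start, method="L-BFGS-B",
                                    options={"maxiter": self.maxiter,
                                             "ftol": self.tol})
            n_used += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise HmmError("all HMM restarts failed to produce a finite likelihood")

        params = _theta_to_params(best.x)
        if params.mu[STATIONARY] > params.mu[TRANSIENT]:
            params = _swap_states(params)
        self.params_ = params
        self.log_likelihood_ = -float(best.fun)
        self.converged_ = bool(best.success)
        self.n_restarts_used_ = n_used
        return self

    def predict(self, steps: pd.DataFrame) -> np.ndarray:
        """Viterbi-decoded state name per step."""
        check_is_fitted(self, "params_")
        return STATE_NAMES[viterbi(self.params_, steps)]

    def score(self, steps: pd.DataFrame, y=None) -> float:
        check_is_fitted(self, "params_")
        return forward_loglik(self.params_, steps)


def _swap_states(p: HmmParams) -> HmmParams:
    sw = np.array([1, 0])
    return HmmParams(mu=p.mu[sw], sigma=p.sigma[sw], kappa=p.kappa[sw],
                     tpm=p.tpm[np.ix_(sw, sw)])


def fit_hmm(steps: pd.DataFrame, restarts: int = 5, rng_seed=None) -> StepHMM:
    """Fit the 2-state HMM and attach decoded states; functional wrapper."""
    model = StepHMM(n_restarts=restarts, random_state=rng_seed)
    model.fit(steps)
    model.decoded_ = model.predict(steps)
    return model
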