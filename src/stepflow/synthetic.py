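"""Ground-truth-labelled synthetic tracking data.

The generator emulates the data a solar GPS/accelerometer tag on a
ground-dwelling forest bird produces, with every latent quantity recorded so
the pipeline can be scored against truth:

* an **activity process** per individual — a two-state (active/resting)
  Markov chain at 1-min resolution whose target activity probability follows
  a diel cycle (morning peak) whose amplitude fades toward the summer
  solstice, mimicking the near-continuous daylight of high latitudes;
* **movement**: during active spells a 2-state Markov chain (stationary /
  transient) emits 5-min steps with gamma lengths and von Mises turns;
  resting intervals produce only a small positive "shuffle" displacement
  (default 0.5 m — perch adjustments, never exactly zero so the gamma
  support holds);
* **observation**: bivariate normal GPS error is added to every true
  position and fixes drop out independently, fragmenting bursts;
* **accelerometer bursts** every 3 min (10 s at 20 Hz): a constant gravity
  vector plus Gaussian dynamic noise whose amplitude depends on the activity
  state;
* **covariate rasters** at 25 m: spatially autocorrelated stand variables,
  the nine-class land cover, turbine visibility counts on flat terrain,
  exponentially decaying shadow-hour surfaces, and distance to access roads.

Default magnitudes are chosen to resemble published capercaillie tracking
summaries: mean observed step length near 12 m per 5-min interval, GPS error
of 10 m SD, and a transient state roughly an order of magnitude faster than
the stationary state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .covariates import derive_land_cover
from .hmm import HmmParams
from .io import CovariateGrid

TWO_PI = 2 * np.pi


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimConfig:
    """Study conditions for the synthetic tag data."""

    n_individuals: int = 13
    start_date: str = "2017-04-23"
    n_days: int = 108                      # 23 April .. 8 August
    fix_interval: float = 300.0
    acc_interval: float = 180.0
    p_missing_fix: float = 0.05
    sigma_gps: float = 5.0                 # m, per coordinate
    # movement states: 0 stationary, 1 transient
    state_mu: tuple = (2.0, 25.0)          # gamma mean step length, m
    state_sigma: tuple = (2.0, 20.0)       # gamma sd, m
    state_kappa: tuple = (0.3, 2.0)        # von Mises concentration
    tpm: tuple = ((0.9, 0.1), (0.15, 0.85))
    resting_scale: float = 0.5             # m, true displacement while resting
    # diel activity schedule
    activity_persistence: float = 0.96     # per-minute stay probability weight
    diel_peak_hour: float = 6.0
    diel_amplitude: float = 1.5            # logit scale
    solstice_day: int = 172
    # accelerometer
    acc_hz: float = 20.0
    acc_burst_seconds: float = 10.0
    a_active: float = 0.8                  # dynamic noise sd, active
    a_rest: float = 0.08
    gravity: tuple = (0.0, 0.0, 1.0)       # static vector, sensor units
    # covariate landscape
    grid_n: int = 200                      # cells per side
    cell_size: float = 25.0
    autocorr_cells: float = 4.0            # Gaussian filter sd, cells
    n_turbines: int = 10
    visibility_radius: float = 2000.0      # m
    # optional land-cover effect on log step-length mean (exp multipliers)
    land_cover_speed_effects: dict = field(default_factory=dict)

    @property
    def hmm_params(self) -> HmmParams:
        return HmmParams(mu=self.state_mu, sigma=self.state_sigma,
                         kappa=self.state_kappa, tpm=np.asarray(self.tpm))

    @property
    def extent(self) -> float:
        return self.grid_n * self.cell_size


def diel_activity_probability(hour, julian_day, config: SimConfig):
    """Target probability of being active as a function of time of year/day."""
    season = np.clip(np.abs(np.asarray(julian_day) - config.solstice_day) / 50.0,
                     0.2, 1.0)
    logit = config.diel_amplitude * season * np.cos(
        TWO_PI * (np.asarray(hour) - config.diel_peak_hour) / 24.0)
    return special.expit(logit)


def simulate_activity_timeline(config: SimConfig, rng, individual: str,
                               times: pd.DatetimeIndex) -> np.ndarray:
    """Persistent active/resting chain at the timeline's resolution."""
    hours = times.hour + times.minute / 60.0 + times.second / 3600.0
    p = diel_activity_probability(hours.to_numpy(), times.dayofyear.to_numpy(),
                                  config)
    rho = config.activity_persistence
    active = np.empty(len(times), dtype=bool)
    u = rng.random(len(times))
    active[0] = u[0] < p[0]
    for t in range(1, len(times)):
        p_next = rho * active[t - 1] + (1 - rho) * p[t]
        active[t] = u[t] < p_next
    return active


def simulate_hmm_steps(params: HmmParams, n_steps: int, burst_length: int = 100,
                       rng=None, individual_id: str = "sim") -> pd.DataFrame:
    """Pure draw from the 2-state step/turn HMM (no observation noise).

    Returns a step table (burst_id, S, alpha_signed, true_state) suitable for
    parameter-recovery experiments; each burst restarts from the stationary
    distribution and its first step has a missing turning angle.
    """
    rng = _rng(rng)
    rows = []
    burst = 0
    remaining = n_steps
    t0 = pd.Timestamp("2017-05-01", tz="UTC")
    while remaining > 0:
        T = min(burst_length, remaining)
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(2, p=params.delta)
        for t in range(1, T):
            states[t] = rng.choice(2, p=params.tpm[states[t - 1]])
        shape = (params.mu / params.sigma) ** 2
        scale = params.sigma ** 2 / params.mu
        s = rng.gamma(shape[states], scale[states])
        alpha = rng.vonmises(0.0, np.maximum(params.kappa[states], 1e-12))
        alpha[0] = np.nan
        t_start = t0 + pd.to_timedelta(np.arange(T) * 300, unit="s")
        rows.append(pd.DataFrame({
            "individual_id": individual_id, "burst_id": burst,
            "t_start": t_start, "t_end": t_start + pd.Timedelta(seconds=300),
            "S": s, "alpha_signed": alpha, "alpha_abs": np.abs(alpha),
            "true_state": states,
        }))
        t0 = t_start[-1] + pd.Timedelta(days=1)
        burst += 1
        remaining -= T
    return pd.concat(rows, ignore_index=True)


def simulate_tracks(config: SimConfig, rng=None, grids=None):
    """Simulate observed fixes plus per-step truth for all individuals.

    Returns ``(fixes, truth, timelines)``: the fixes table
    (individual_id, timestamp, x, y), a truth table aligned with every
    schedule-adjacent pair of retained fixes, and the 1-min activity
    timeline per individual (used again for the accelerometer).

    When ``grids`` (with a ``land_cover`` layer) and
    ``config.land_cover_speed_effects`` are supplied, the log mean step
    length is shifted by the class effect at the bird's current true
    position, injecting a known habitat effect.
    """
    rng = _rng(rng)
    params = config.hmm_params
    start = pd.Timestamp(config.start_date, tz="UTC")
    minutes = pd.date_range(start, start + pd.Timedelta(days=config.n_days),
                            freq="1min", inclusive="left")
    fix_stride = int(config.fix_interval // 60)
    lc_grid = (grids or {}).get("land_cover")
    effects = config.land_cover_speed_effects
    margin = 4 * config.cell_size
    lo, hi = margin, config.extent - margin

    fixes_rows, truth_rows, timelines = [], [], {}
    for i in range(config.n_individuals):
        ind = f"bird{i + 1:02d}"
        active_min = simulate_activity_timeline(config, rng, ind, minutes)
        timelines[ind] = pd.DataFrame({"individual_id": ind, "t": minutes,
                                       "active": active_min})
        fix_times = minutes[::fix_stride]
        fix_active = active_min[::fix_stride]
        n_fix = len(fix_times)
        n_int = n_fix - 1

        # movement-state chain over intervals
        states = np.empty(n_int, dtype=int)
        states[0] = rng.choice(2, p=params.delta)
        for t in range(1, n_int):
            states[t] = rng.choice(2, p=params.tpm[states[t - 1]])
        interval_active = fix_active[:-1] & fix_active[1:]

        shape = (params.mu / params.sigma) ** 2
        scale = params.sigma ** 2 / params.mu
        pos = np.empty((n_fix, 2))
        pos[0] = rng.uniform(0.35 * config.extent, 0.65 * config.extent, 2)
        heading = rng.uniform(-np.pi, np.pi)
        turns = rng.vonmises(0.0, np.maximum(params.kappa[states], 1e-12))
        rest_len = rng.gamma(4.0, config.resting_scale / 4.0, n_int)
        rest_dir = rng.uniform(-np.pi, np.pi, n_int)
        gamma_u = rng.gamma(shape[states], 1.0, n_int)   # scaled below

        true_disp = np.empty(n_int)
        for t in range(n_int):
            if interval_active[t]:
                mult = 1.0
                if lc_grid is not None and effects:
                    code = lc_grid.value_at(pos[t, 0], pos[t, 1])
                    if np.isfinite(code):
                        label = lc_grid.categories.get(int(code), "")
                        mult = np.exp(effects.get(label, 0.0))
                step = gamma_u[t] * scale[states[t]] * mult
                heading = heading + turns[t]
            else:
                step = rest_len[t]
                heading = rest_dir[t]
            true_disp[t] = step
            nxt = pos[t] + step * np.array([np.cos(heading), np.sin(heading)])
            # reflect at the landscape margin to stay on the covariate grids
            for d in range(2):
                if nxt[d] < lo:
                    nxt[d] = lo + (lo - nxt[d])
                elif nxt[d] > hi:
                    nxt[d] = hi - (nxt[d] - hi)
            pos[t + 1] = nxt

        err = rng.normal(0.0, config.sigma_gps, (n_fix, 2))
        obs = pos + err
        retained = rng.random(n_fix) >= config.p_missing_fix

        fixes_rows.append(pd.DataFrame({
            "individual_id": ind,
            "timestamp": fix_times[retained],
            "x": obs[retained, 0], "y": obs[retained, 1],
        }))
        # truth for schedule-adjacent retained pairs
        pair_ok = retained[:-1] & retained[1:]
        ev = err[1:] - err[:-1]
        truth_rows.append(pd.DataFrame({
            "individual_id": ind,
            "t_start": fix_times[:-1][pair_ok],
            "true_activity": np.where(interval_active[pair_ok], "active", "resting"),
            "true_movestate": np.where(
                interval_active[pair_ok],
                np.where(states[pair_ok] == 1, "transient", "stationary"),
                "stationary"),
            "true_displacement": true_disp[pair_ok],
            "gps_error_magnitude": np.hypot(ev[pair_ok, 0], ev[pair_ok, 1]),
        }))

    fixes = pd.concat(fixes_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return fixes, truth, timelines


def simulate_acc(config: SimConfig, timelines: dict, rng=None) -> pd.DataFrame:
    """Accelerometer bursts (10 s at 20 Hz every 3 min) from the timelines."""
    rng = _rng(rng)
    n_samp = int(config.acc_hz * config.acc_burst_seconds)
    stride = int(config.acc_interval // 60)
    out = []
    offsets = np.arange(n_samp) / config.acc_hz
    g = np.asarray(config.gravity)
    for ind, tl in timelines.items():
        burst_times = tl["t"].iloc[::stride]
        burst_active = tl["active"].iloc[::stride].to_numpy()
        n_b = len(burst_times)
        amp = np.where(burst_active, config.a_active, config.a_rest)
        noise = rng.normal(0.0, 1.0, (n_b, n_samp, 3)) * amp[:, None, None]
        acc = noise + g[None, None, :]
        out.append(pd.DataFrame({
            "individual_id": ind,
            "burst_start": pd.DatetimeIndex(burst_times).repeat(n_samp),
            "t_offset": np.tile(offsets, n_b),
            "ax": acc[:, :, 0].ravel(),
            "ay": acc[:, :, 1].ravel(),
            "az": acc[:, :, 2].ravel(),
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Covariate landscape
# ---------------------------------------------------------------------------

def _gaussian_field(rng, n, sd_cells) -> np.ndarray:
    """Unit-variance spatially autocorrelated field on an n x n grid."""
    f = ndimage.gaussian_filter(rng.standard_normal((n, n)), sd_cells,
                                mode="wrap")
    return (f - f.mean()) / f.std()


def simulate_covariates(config: SimConfig, rng=None) -> dict:
    """Synthetic covariate rasters sharing one origin/resolution.

    Returns a dict of :class:`CovariateGrid` with the six model layers
    (``land_cover``, ``dbh``, ``tree_height``, ``n_visible_turbines``,
    ``shadow_hours``, ``dist_access_road``) plus the land-cover ingredient
    layers and the turbine coordinates (``turbines`` key, an array).
    """
    rng = _rng(rng)
    n, cell = config.grid_n, config.cell_size

    def grid(name, values, nodata=-9999.0):
        return CovariateGrid(layer_name=name, x0=0.0, y0=0.0, cell_size=cell,
                             values=values, nodata=nodata)

    f_dbh = _gaussian_field(rng, n, config.autocorr_cells)
    f_ht = 0.6 * f_dbh + 0.8 * _gaussian_field(rng, n, config.autocorr_cells)
    dbh = np.clip(20.0 + 8.0 * f_dbh, 1.0, None)
    height = np.clip(14.0 + 5.0 * f_ht, 0.5, None)

    f_base = _gaussian_field(rng, n, 2 * config.autocorr_cells)
    base = np.zeros((n, n))
    q = np.quantile(f_base, [0.02, 0.08, 0.14])
    base[f_base < q[2]] = 4          # forest bog
    base[f_base < q[1]] = 5          # open bog
    base[f_base < q[0]] = 3          # cultivated

    f_cut = _gaussian_field(rng, n, config.autocorr_cells)
    f_age = _gaussian_field(rng, n, 2 * config.autocorr_cells)
    cut = f_cut > np.quantile(f_cut, 0.85)
    age = np.where(cut, np.clip(15.0 + 8.0 * f_age, 0.0, 30.0), np.nan)

    pine = 100.0 * special.expit(1.8 * _gaussian_field(rng, n, config.autocorr_cells))
    spruce = (100.0 - pine) * special.expit(
        1.8 * _gaussian_field(rng, n, config.autocorr_cells))
    inventory = (_gaussian_field(rng, n, config.autocorr_cells)
                 > np.quantile(_gaussian_field(rng, n, config.autocorr_cells), 0.06))

    land_cover = derive_land_cover(
        grid("base_cover", base), grid("pine_pct", pine),
        grid("spruce_pct", spruce),
        grid("clearcut_age", np.where(np.isnan(age), -9999.0, age)),
        grid("inventory", inventory.astype(float)))

    # turbines on flat terrain: visibility is a within-radius count
    extent = config.extent
    turbines = rng.uniform(0.15 * extent, 0.85 * extent,
                           (config.n_turbines, 2))
    yy, xx = np.meshgrid(
        (np.arange(n)[::-1] + 0.5) * cell,   # row 0 = top
        (np.arange(n) + 0.5) * cell, indexing="ij")
    vis = np.zeros((n, n))
    shadow = np.zeros((n, n))
    for tx, ty in turbines:
        d = np.hypot(xx - tx, yy - ty)
        vis += d <= config.visibility_radius
        shadow += 30.0 * np.exp(-d / 300.0)

    # access roads: a polyline through the turbines (ordered by x)
    road_mask = np.zeros((n, n), dtype=bool)
    pts = turbines[np.argsort(turbines[:, 0])]
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        length = np.hypot(x2 - x1, y2 - y1)
        n_pt = max(int(length / (cell / 2)), 2)
        sx = np.linspace(x1, x2, n_pt)
        sy = np.linspace(y1, y2, n_pt)
        col = np.clip((sx / cell).astype(int), 0, n - 1)
        row = np.clip(n - 1 - (sy / cell).astype(int), 0, n - 1)
        road_mask[row, col] = True
    dist_road = ndimage.distance_transform_edt(~road_mask) * cell

    return {
        "land_cover": land_cover,
        "dbh": grid("dbh", dbh),
        "tree_height": grid("tree_height", height),
        "n_visible_turbines": grid("n_visible_turbines", vis),
        "shadow_hours": grid("shadow_hours", shadow),
        "dist_access_road": grid("dist_access_road", dist_road),
        "base_cover": grid("base_cover", base),
        "pine_pct": grid("pine_pct", pine),
        "spruce_pct": grid("spruce_pct", spruce),
        "clearcut_age": grid("clearcut_age", np.where(np.isnan(age), -9999.0, age)),
        "inventory": grid("inventory", inventory.astype(float)),
        "turbines": turbines,
    }


# ---------------------------------------------------------------------------
# Direct analysis-table generator for the regressions
# ---------------------------------------------------------------------------

#: Default injected land-cover effects on log step length (reference:
#: recent clear-cuts), matching the magnitudes a field study reports.
DEFAULT_LC_EFFECTS = {
    "clearcut>5y": 0.120, "cultivated": 0.604, "forest-bog": 0.195,
    "open-bog": 0.380, "mixed-forest": 0.240, "unknown-forest": 0.230,
    "pine-forest": 0.240, "spruce-forest": 0.222,
}

DEFAULT_LC_PROPORTIONS = {
    "clearcut<=5y": 0.10, "clearcut>5y": 0.10, "cultivated": 0.02,
    "forest-bog": 0.08, "open-bog": 0.08, "mixed-forest": 0.17,
    "unknown-forest": 0.05, "pine-forest": 0.25, "spruce-forest": 0.15,
}


def simulate_regression_table(n_steps: int = 2000, n_individuals: int = 13,
                              rng=None, *, intercept: float = 1.891,
                              lc_effects: dict = None,
                              s_prev_coef: float = 0.026,
                              diel_amplitude: float = 0.3,
                              gamma_shape: float = 0.45,
                              individual_sd: float = 0.1,
                              lagged_response: bool = True) -> pd.DataFrame:
    """Analysis-ready step table drawn directly from the regression model.

    The linear predictor contains the land-cover effects, a seasonally
    modulated diel cosine (amplitude grows quadratically with distance from
    the solstice, day 172, so the diel pattern is exactly flat at midsummer),
    the lag covariate, and i.i.d. individual intercepts; the five continuous
    habitat/turbine covariates are generated but given **zero** effect, so
    shrinkage smooths fitted to them should vanish.

    With ``lagged_response`` (the default) steps are generated sequentially
    within bursts and ``S_prev`` is the realised previous step length, so the
    response carries genuine lag-1 autocorrelation that the lag covariate
    removes.  The feedback covariate is truncated at ``lag_cap`` meters: a
    log-linear lag effect with heavy-tailed multiplicative noise is otherwise
    supercritical, whereas real step lengths are physically bounded.

    Returns a table with the truth column ``eta_true`` and the drawn
    covariates, ready for the model fitters.
    """
    lag_cap = 60.0
    rng = _rng(rng)
    lc_effects = DEFAULT_LC_EFFECTS if lc_effects is None else lc_effects
    labels = list(DEFAULT_LC_PROPORTIONS)
    probs = np.array(list(DEFAULT_LC_PROPORTIONS.values()))
    lc = rng.choice(labels, n_steps, p=probs / probs.sum())
    ind = rng.choice([f"bird{i + 1:02d}" for i in range(n_individuals)], n_steps)
    b_ind = dict(zip([f"bird{i + 1:02d}" for i in range(n_individuals)],
                     rng.normal(0, individual_sd, n_individuals)))
    df = pd.DataFrame({
        "individual_id": ind,
        "land_cover": lc,
        "dbh": rng.normal(20, 8, n_steps).clip(1),
        "tree_height": rng.normal(14, 5, n_steps).clip(0.5),
        "n_visible_turbines": rng.integers(0, 11, n_steps).astype(float),
        "shadow_hours": rng.gamma(1.5, 10.0, n_steps),
        "dist_access_road": rng.uniform(0, 3000, n_steps),
        "daytime": rng.uniform(0, 24, n_steps),
        "julian_day": rng.integers(113, 221, n_steps).astype(float),
    })
    season = ((df["julian_day"] - 172) / 59.0) ** 2
    eta_base = (intercept
                + np.array([lc_effects.get(c, 0.0) for c in lc])
                + diel_amplitude * season
                * np.cos(TWO_PI * (df["daytime"] - 5) / 24)
                + np.array([b_ind[i] for i in ind])).to_numpy()
    s_prev_center = np.exp(intercept + 0.2)   # rough long-run mean step length
    burst = np.arange(n_steps) // 50
    if lagged_response:
        gamma_u = rng.gamma(gamma_shape, 1.0 / gamma_shape, n_steps)
        s = np.empty(n_steps)
        s_prev = np.empty(n_steps)
        for i in range(n_steps):
            s_prev[i] = (min(s[i - 1], lag_cap)
                         if i > 0 and burst[i] == burst[i - 1]
                         else s_prev_center)
            eta_i = eta_base[i] + s_prev_coef * (s_prev[i] - s_prev_center)
            s[i] = np.exp(eta_i) * gamma_u[i]
        df["S_prev"] = s_prev
        eta = eta_base + s_prev_coef * (s_prev - s_prev_center)
        df["S"] = s
    else:
        df["S_prev"] = rng.gamma(1.0, s_prev_center, n_steps)
        eta = eta_base + s_prev_coef * (df["S_prev"].to_numpy() - s_prev_center)
        df["S"] = rng.gamma(gamma_shape, np.exp(eta) / gamma_shape)
    df["alpha_abs"] = np.minimum(
        rng.gamma(4.0, np.exp(0.63 - 0.1 * (lc == "open-bog")) / 4.0), np.pi)
    df["eta_true"] = np.asarray(eta)
    df["included"] = True
    # burst bookkeeping so the autocorrelation helpers work
    df["burst_id"] = burst
    t0 = pd.Timestamp("2017-05-01", tz="UTC")
    df["t_start"] = t0 + pd.to_timedelta(np.arange(n_steps) * 300, unit="s")
    df["t_end"] = df["t_start"] + pd.Timedelta(seconds=300)
    return df
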