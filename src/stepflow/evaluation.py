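"""Ground-truth validation experiments on synthetic data.

Each function runs one self-contained experiment against the generators in
:mod:`stepflow.synthetic` and returns a dict of scalar metrics:

* exactness of the HMM forward likelihood and Viterbi decoding against
  brute-force path enumeration on short bursts;
* recovery of the movement-state parameters from repeated simulations;
* precision of the false-movement (resting-transient) exclusion and
  step-level activity-label agreement, scored against the generator's truth;
* recovery of an injected land-cover effect and shrinkage of null-covariate
  smooths in the speed regression, plus cyclic continuity of the diel smooth;
* exact record conservation through the pipeline manifest.

All experiments are seeded and deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import activity, fusion, hmm, models, steps, synthetic
from .config import RunConfig


def hmm_exactness(n_bursts: int = 200, max_len: int = 10, seed: int = 0) -> dict:
    """Forward loglik and Viterbi vs brute-force enumeration on toy bursts.

    Bursts of 2..max_len steps are drawn from one parameter set and scored
    under a *different* random parameter set each time, so agreement is not
    an artefact of evaluating at the generating parameters.
    """
    rng = np.random.default_rng(seed)
    gen = synthetic.SimConfig().hmm_params
    max_dev = 0.0
    n_steps_total = 0
    n_path_agree = 0
    for _ in range(n_bursts):
        p, q = rng.uniform(0.55, 0.95, 2)
        mu = np.sort(rng.uniform(1, 40, 2))
        test_params = hmm.HmmParams(
            mu=mu, sigma=rng.uniform(0.5, 1.5, 2) * mu,
            kappa=rng.uniform(0.05, 3.0, 2), tpm=[[p, 1 - p], [1 - q, q]])
        T = int(rng.integers(2, max_len + 1))
        burst = synthetic.simulate_hmm_steps(gen, T, burst_length=T, rng=rng)
        dev = abs(hmm.forward_loglik(test_params, burst)
                  - hmm.brute_force_loglik(test_params, burst))
        max_dev = max(max_dev, dev)
        path = hmm.viterbi(test_params, burst)
        ref = hmm.brute_force_viterbi(test_params, burst)
        n_path_agree += int((path == ref).all())
        n_steps_total += T
    return {
        "loglik_max_abs_dev": max_dev,
        "viterbi_burst_agreement_pct": 100.0 * n_path_agree / n_bursts,
        "n": n_steps_total,
    }


def hmm_parameter_recovery(n_sims: int = 20, n_steps: int = 5000,
                           seed: int = 0, restarts: int = 3) -> dict:
    """Median relative parameter errors over repeated simulate-and-fit runs."""
    truth = synthetic.SimConfig().hmm_params
    rel_mu, rel_sigma, rel_kappa, abs_tpm = [], [], [], []
    for r in range(n_sims):
        rng = np.random.default_rng(seed + 1000 * r)
        data = synthetic.simulate_hmm_steps(truth, n_steps, burst_length=100,
                                            rng=rng)
        fit = hmm.StepHMM(n_restarts=restarts, random_state=seed + r).fit(data)
        p = fit.params_
        rel_mu.append(np.abs(p.mu - truth.mu) / truth.mu)
        rel_sigma.append(np.abs(p.sigma - truth.sigma) / truth.sigma)
        rel_kappa.append(np.abs(p.kappa - truth.kappa) / truth.kappa)
        abs_tpm.append(np.abs(p.tpm - truth.tpm).max())
    return {
        "mu_median_rel_err_pct": 100.0 * float(np.median(rel_mu)),
        "sigma_median_rel_err_pct": 100.0 * float(np.median(rel_sigma)),
        "kappa_median_rel_err_pct": 100.0 * float(np.median(rel_kappa)),
        "tpm_median_max_abs_err": float(np.median(abs_tpm)),
        "n": n_sims * n_steps,
    }


def classification_experiment(seed: int = 0, n_individuals: int = 4,
                              n_days: int = 10, sigma_gps: float = 10.0,
                              restarts: int = 2) -> dict:
    """Run classification + filtering on tracks with known truth.

    Returns step-level activity agreement, the precision of the
    resting-transient exclusion (fraction of excluded steps that are truly
    resting), and the mean observed step length of included steps.
    """
    cfg = synthetic.SimConfig(n_individuals=n_individuals, n_days=n_days,
                              sigma_gps=sigma_gps, p_missing_fix=0.03)
    rng = np.random.default_rng(seed)
    fixes, truth, timelines = synthetic.simulate_tracks(cfg, rng)
    acc = synthetic.simulate_acc(cfg, timelines, rng)

    rc = RunConfig(rng_seed=seed, hmm_restarts=restarts)
    fixes = steps.filter_bursts(steps.segment_bursts(fixes, rc),
                                rc.min_burst_fixes)
    table = steps.build_steps(fixes)
    dba = activity.smooth_activity(activity.compute_dba(acc),
                                   rc.smoothing_window)
    phases = activity.classify_phases(dba, rc)
    table = activity.label_step_activity(table, phases)
    model = hmm.fit_hmm(table, restarts=restarts, rng_seed=seed)
    table["movestate"] = model.decoded_
    labelled, report = fusion.fuse_and_filter(table)
    merged = labelled.merge(truth, on=["individual_id", "t_start"], how="left")

    known = merged[merged["activity"] != "unknown"]
    agreement = float((known["activity"] == known["true_activity"]).mean())
    excluded = merged[merged["fused"] == "resting-transient"]
    precision = float((excluded["true_activity"] == "resting").mean())
    frac_imputed = fusion.recompute_lag(labelled).attrs["s_prev_imputed_fraction"]
    return {
        "activity_agreement_pct": 100.0 * agreement,
        "false_movement_precision_pct": 100.0 * precision,
        "n_excluded": int(len(excluded)),
        "mean_step_length_m": float(merged.loc[merged["included"], "S"].mean()),
        "s_prev_imputed_pct": 100.0 * float(frac_imputed),
        "n": int(report.n_input),
    }


NULL_SMOOTHS = ["s(dbh)", "s(tree_height)", "s(n_visible_turbines)",
                "s(shadow_hours)", "s(dist_access_road)"]


def regression_recovery(n_reps: int = 20, n_steps: int = 3000,
                        seed: int = 0) -> dict:
    """Replicated recovery of the injected open-bog effect exp(0.38).

    Reports 2-SE coverage of the injected contrast, the fraction of
    null-covariate shrinkage smooths attaining < 0.5 effective df, and the
    worst cyclic-continuity gap of the diel smooth at 0/24 h.
    """
    covered, shrunk, gaps = [], [], []
    for r in range(n_reps):
        rng = np.random.default_rng(seed + 1000 * r)
        df = synthetic.simulate_regression_table(n_steps, rng=rng)
        fit = models.fit_speed_model(df, check_lag_baseline=False)
        tab = fit.coef_table.set_index("term")
        est = tab.loc["land_cover[open-bog]", "estimate"]
        se = tab.loc["land_cover[open-bog]", "se"]
        covered.append(abs(est - 0.380) < 2 * se)
        edf = fit.smooth_table.set_index("term")["edf"]
        shrunk.extend(bool(edf[s] < 0.5) for s in NULL_SMOOTHS)
        base = {c: [df[c].mean()] for c in
                ("S_prev", "dbh", "tree_height", "n_visible_turbines",
                 "shadow_hours", "dist_access_road")}
        base["land_cover"] = [fit.model.terms[0].levels_[0]]
        base["individual_id"] = ["__population__"]
        base["julian_day"] = [140.0]
        lo = fit.model.predict(pd.DataFrame(dict(base, daytime=[0.0])))
        hi = fit.model.predict(pd.DataFrame(dict(base, daytime=[24.0])))
        gaps.append(abs(float(lo[0]) - float(hi[0])))
    return {
        "openbog_2se_coverage_pct": 100.0 * float(np.mean(covered)),
        "null_smooth_shrunk_pct": 100.0 * float(np.mean(shrunk)),
        "cyclic_continuity_max_gap": float(np.max(gaps)),
        "n": n_reps * n_steps,
    }


def conservation_check(seed: int = 0, tmp_dir=None) -> dict:
    """Record conservation and stage chaining on a small pipeline run."""
    import tempfile

    from .pipeline import run_pipeline, simulate_to_dir

    cfg = synthetic.SimConfig(n_individuals=2, n_days=5, p_missing_fix=0.02)
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        simulate_to_dir(cfg, td, seed=seed)
        rc = RunConfig(rng_seed=seed, hmm_restarts=1,
                       post_capture_exclusion_days=1.0)
        res = run_pipeline(td, rc, fit_models=False)
    stages = res["manifest"].stages
    n_violations = sum(s["n_in"] != s["n_out"] + s["n_excluded"] for s in stages)
    n_chain_breaks = sum(a["n_out"] != b["n_in"]
                         for a, b in zip(stages[:-1], stages[1:]))
    table = res["steps"]
    return {
        "conservation_violations": int(n_violations),
        "chain_breaks": int(n_chain_breaks),
        # calibration aid: mean observed step length under default conditions
        "mean_step_length_m": float(table.loc[table["included"], "S"].mean()),
        "n": int(stages[0]["n_in"]),
    }
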