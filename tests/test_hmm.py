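import numpy as np
import pandas as pd
import pytest

from stepflow.hmm import (HmmParams, StepHMM, brute_force_loglik,
                          brute_force_viterbi, fit_hmm, forward_loglik,
                          stationary_distribution, viterbi)
from stepflow.synthetic import simulate_hmm_steps


def _rand_params(rng) -> HmmParams:
    mu = np.sort(rng.uniform(1, 40, 2))
    p, q = rng.uniform(0.55, 0.95, 2)
    return HmmParams(mu=mu, sigma=rng.uniform(0.5, 1.5, 2) * mu,
                     kappa=rng.uniform(0.05, 3.0, 2),
                     tpm=[[p, 1 - p], [1 - q, q]])


class TestForwardAlgorithm:
    def test_single_step_uniform_angle_closed_form(self):
        from scipy import stats
        p = HmmParams(mu=[2, 20], sigma=[2, 15], kappa=[0.0, 0.0],
                      tpm=[[0.9, 0.1], [0.2, 0.8]])
        steps = pd.DataFrame({"burst_id": [0], "S": [7.0],
                              "alpha_signed": [0.5]})
        dens = sum(
            p.delta[k] * stats.gamma.pdf(7.0, a=(p.mu[k] / p.sigma[k]) ** 2,
                                         scale=p.sigma[k] ** 2 / p.mu[k])
            / (2 * np.pi)
            for k in range(2))
        assert forward_loglik(p, steps) == pytest.approx(np.log(dens), abs=1e-10)

    def test_matches_brute_force_on_random_toy_bursts(self, toy_hmm_params):
        rng = np.random.default_rng(11)
        for trial in range(20):
            p = _rand_params(rng)
            steps = simulate_hmm_steps(toy_hmm_params,
                                       int(rng.integers(8, 30)),
                                       burst_length=int(rng.integers(2, 9)),
                                       rng=rng)
            assert forward_loglik(p, steps) == pytest.approx(
                brute_force_loglik(p, steps), abs=1e-8)

    def test_two_identical_bursts_double_the_loglik(self, toy_hmm_params):
        rng = np.random.default_rng(5)
        one = simulate_hmm_steps(toy_hmm_params, 6, burst_length=6, rng=rng)
        two = pd.concat([one, one.assign(burst_id=1)], ignore_index=True)
        assert forward_loglik(toy_hmm_params, two) == pytest.approx(
            2 * forward_loglik(toy_hmm_params, one), rel=1e-12)

    def test_invariant_to_burst_order(self, toy_hmm_params):
        rng = np.random.default_rng(6)
        steps = simulate_hmm_steps(toy_hmm_params, 30, burst_length=10, rng=rng)
        shuffled = pd.concat(
            [grp for _, grp in sorted(steps.groupby("burst_id"),
                                      key=lambda kv: -kv[0])],
            ignore_index=True)
        assert forward_loglik(toy_hmm_params, shuffled) == pytest.approx(
            forward_loglik(toy_hmm_params, steps), rel=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            HmmParams(mu=[1, 2], sigma=[0.0, 1.0], kappa=[1, 1],
                      tpm=[[0.5, 0.5], [0.5, 0.5]])


class TestViterbi:
    def test_matches_exhaustive_argmax(self, toy_hmm_params):
        rng = np.random.default_rng(21)
        for trial in range(15):
            p = _rand_params(rng)
            steps = simulate_hmm_steps(toy_hmm_params,
                                       int(rng.integers(6, 17)),
                                       burst_length=8, rng=rng)
            np.testing.assert_array_equal(viterbi(p, steps),
                                          brute_force_viterbi(p, steps))

    def test_single_step_burst_is_pointwise_argmax(self):
        p = HmmParams(mu=[2, 20], sigma=[2, 15], kappa=[0.5, 1.5],
                      tpm=[[0.9, 0.1], [0.2, 0.8]])
        short = pd.DataFrame({"burst_id": [0], "S": [1.0],
                              "alpha_signed": [np.nan]})
        long = pd.DataFrame({"burst_id": [0], "S": [60.0],
                             "alpha_signed": [np.nan]})
        assert viterbi(p, short)[0] == 0
        assert viterbi(p, long)[0] == 1

    def test_sharp_turn_small_step_decoded_stationary(self):
        """One tight turn with a tiny step amid long straight steps."""
        p = HmmParams(mu=[2, 30], sigma=[2, 10], kappa=[0.1, 15.0],
                      tpm=[[0.8, 0.2], [0.2, 0.8]])
        steps = pd.DataFrame({
            "burst_id": 0,
            "S": [30.0, 31.0, 1.5, 29.0, 30.0],
            "alpha_signed": [np.nan, 0.05, 3.0, -0.02, 0.01],
        })
        path = viterbi(p, steps)
        np.testing.assert_array_equal(path, brute_force_viterbi(p, steps))
        assert path[2] == 0 and path[1] == 1


class TestFitting:
    def test_parameter_recovery_from_known_model(self, toy_hmm_params):
        steps = simulate_hmm_steps(toy_hmm_params, 10_000, burst_length=100,
                                   rng=np.random.default_rng(42))
        fit = StepHMM(n_restarts=2, random_state=0).fit(steps)
        np.testing.assert_allclose(fit.params_.mu, toy_hmm_params.mu, rtol=0.05)
        np.testing.assert_allclose(fit.params_.tpm, toy_hmm_params.tpm,
                                   atol=0.05)

    def test_label_convention_transient_has_larger_mean(self, toy_hmm_params):
        steps = simulate_hmm_steps(toy_hmm_params, 2000, rng=np.random.default_rng(1))
        fit = StepHMM(n_restarts=1, random_state=0).fit(steps)
        assert fit.params_.mu[1] > fit.params_.mu[0]

    def test_restart_stability_on_well_separated_data(self, toy_hmm_params):
        steps = simulate_hmm_steps(toy_hmm_params, 3000, rng=np.random.default_rng(2))
        ll = [StepHMM(n_restarts=r, random_state=3).fit(steps).log_likelihood_
              for r in (1, 6)]
        assert abs(ll[0] - ll[1]) < 1e-4 * abs(ll[0])

    def test_degenerate_identical_states_match_single_state_fit(self):
        """Both states identical: the 2-state likelihood collapses to 1 state."""
        from scipy import stats
        rng = np.random.default_rng(3)
        same = HmmParams(mu=[8.0, 8.0], sigma=[6.0, 6.0], kappa=[1.0, 1.0],
                         tpm=[[0.5, 0.5], [0.5, 0.5]])
        steps = simulate_hmm_steps(same, 2000, rng=rng)
        fit = StepHMM(n_restarts=2, random_state=4).fit(steps)
        # independent single-state ML fit: gamma for S, von Mises for alpha
        s = steps["S"].to_numpy()
        a, loc, scale = stats.gamma.fit(s, floc=0)
        ll1 = stats.gamma.logpdf(s, a, scale=scale).sum()
        alpha = steps["alpha_signed"].dropna().to_numpy()
        kappa, loc_, scale_ = stats.vonmises.fit(alpha, fscale=1)
        ll1 += stats.vonmises.logpdf(alpha, kappa, loc=loc_).sum()
        assert fit.log_likelihood_ >= ll1 - 2.0

    def test_decoded_states_attached_by_wrapper(self, toy_hmm_params):
        steps = simulate_hmm_steps(toy_hmm_params, 1000, rng=np.random.default_rng(5))
        model = fit_hmm(steps, restarts=1, rng_seed=0)
        assert set(model.decoded_) <= {"stationary", "transient"}
        truth = np.where(steps["true_state"] == 1, "transient", "stationary")
        assert (model.decoded_ == truth).mean() > 0.9

    def test_sklearn_param_interface(self):
        model = StepHMM(n_restarts=3, random_state=7)
        assert model.get_params()["n_restarts"] == 3
        model.set_params(n_restarts=1)
        assert model.n_restarts == 1


def test_stationary_distribution_balances_transitions():
    tpm = np.array([[0.9, 0.1], [0.3, 0.7]])
    delta = stationary_distribution(tpm)
    np.testing.assert_allclose(delta @ tpm, delta, atol=1e-12)
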