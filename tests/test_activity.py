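import numpy as np
import pandas as pd
import pytest

from stepflow.activity import (ActivityThresholdSegmenter, classify_phases,
                               compute_dba, label_step_activity, otsu_threshold,
                               smooth_activity)


def make_acc_burst(ax, ay, az, individual="a", start="2017-05-01T00:00:00Z"):
    n = len(ax)
    return pd.DataFrame({
        "individual_id": individual,
        "burst_start": pd.Timestamp(start),
        "t_offset": np.arange(n) * 0.05,
        "ax": ax, "ay": ay, "az": az,
    })


def make_dba_series(values, individual="a", interval_s=180):
    t0 = pd.Timestamp("2017-05-01T00:00:00Z")
    return pd.DataFrame({
        "individual_id": individual,
        "t": [t0 + pd.Timedelta(seconds=interval_s * i)
              for i in range(len(values))],
        "dba": np.asarray(values, dtype=float),
    })


class TestComputeDba:
    def test_constant_signal_has_zero_dba(self):
        acc = make_acc_burst(np.full(200, 0.3), np.full(200, -0.1),
                             np.full(200, 1.0))
        out = compute_dba(acc)
        assert out["dba"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_unit_signal_gives_unit_dba(self):
        ax = np.tile([1.0, -1.0], 100)          # mean 0, |dynamic| = 1
        acc = make_acc_burst(ax, np.zeros(200), np.ones(200))
        out = compute_dba(acc)
        assert out["dba"].iloc[0] == pytest.approx(1.0)

    def test_linearity_in_dynamic_amplitude(self):
        rng = np.random.default_rng(0)
        dyn = rng.normal(size=200)
        a1 = compute_dba(make_acc_burst(dyn, np.zeros(200), np.ones(200)))
        a2 = compute_dba(make_acc_burst(2 * dyn, np.zeros(200), np.ones(200)))
        assert a2["dba"].iloc[0] == pytest.approx(2 * a1["dba"].iloc[0])

    def test_invariant_to_per_axis_constant_offset(self):
        rng = np.random.default_rng(1)
        dyn = rng.normal(size=(200, 3))
        base = compute_dba(make_acc_burst(*dyn.T))
        shifted = compute_dba(make_acc_burst(dyn[:, 0] + 9.81, dyn[:, 1] - 2.0,
                                             dyn[:, 2] + 0.5))
        assert shifted["dba"].iloc[0] == pytest.approx(base["dba"].iloc[0])

    def test_value_sits_at_burst_midpoint(self):
        acc = make_acc_burst(np.zeros(200), np.zeros(200), np.ones(200))
        out = compute_dba(acc)
        expected = pd.Timestamp("2017-05-01T00:00:00Z") + pd.Timedelta(
            seconds=199 * 0.05 / 2)
        assert out["t"].iloc[0] == expected


class TestSmoothing:
    def test_window_one_is_identity(self):
        s = make_dba_series([0.1, 5.0, 0.2])
        out = smooth_activity(s, 1)
        np.testing.assert_allclose(out["dba_smooth"], out["dba"])

    def test_centered_mean(self):
        out = smooth_activity(make_dba_series([0.0, 3.0, 0.0]), 3)
        assert out["dba_smooth"].iloc[1] == pytest.approx(1.0)
        # edges shrink the window
        assert out["dba_smooth"].iloc[0] == pytest.approx(1.5)

    def test_constant_series_unchanged(self):
        out = smooth_activity(make_dba_series([2.0] * 10), 3)
        np.testing.assert_allclose(out["dba_smooth"], 2.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_activity(make_dba_series([1, 2, 3]), 2)


class TestThreshold:
    def test_bimodal_series_split_between_modes(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0.01, 0.002, 50),
                               rng.normal(1.0, 0.05, 50)])
        thr = otsu_threshold(vals)
        assert 0.02 < thr < 0.9

    def test_degenerate_series_returns_none(self):
        assert otsu_threshold(np.zeros(30)) is None

    def test_phases_recover_run_labels_exactly(self):
        truth = np.r_[np.zeros(30), np.ones(25), np.zeros(45)]
        rng = np.random.default_rng(3)
        vals = np.where(truth > 0, 1.0, 0.01) * (1 + 0.05 * rng.normal(size=100))
        series = smooth_activity(make_dba_series(vals), 1)
        seg = ActivityThresholdSegmenter(window=1).fit(series)
        pred = seg.predict(series[["individual_id", "t"]])
        assert (pred == np.where(truth > 0, "active", "resting")).mean() == 1.0

    def test_all_zero_series_single_resting_phase(self):
        series = smooth_activity(make_dba_series([0.0] * 30), 3)
        phases = ActivityThresholdSegmenter().fit(series).phases_
        assert len(phases) == 1
        assert phases["state"].iloc[0] == "resting"

    def test_higher_mode_is_active_regardless_of_which_comes_first(self):
        # same boundary structure whether the series starts high or low
        low_first = make_dba_series([0.01] * 30 + [1.0] * 30)
        high_first = make_dba_series([1.0] * 30 + [0.01] * 30)
        ph1 = classify_phases(smooth_activity(low_first, 1))
        ph2 = classify_phases(smooth_activity(high_first, 1))
        assert list(ph1["state"]) == ["resting", "active"]
        assert list(ph2["state"]) == ["active", "resting"]

    def test_phases_partition_time_span(self, small_sim, run_config):
        from stepflow.activity import compute_dba, smooth_activity
        dba = smooth_activity(compute_dba(small_sim["acc"]),
                              run_config.smoothing_window)
        phases = classify_phases(dba, run_config)
        for _, ph in phases.groupby("individual_id"):
            ph = ph.sort_values("t_start")
            # contiguous: each phase starts where the previous one ends
            assert (ph["t_start"].iloc[1:].to_numpy()
                    == ph["t_end"].iloc[:-1].to_numpy()).all()
            # alternating labels
            assert (ph["state"].iloc[1:].to_numpy()
                    != ph["state"].iloc[:-1].to_numpy()).all()


class TestStepLabelling:
    @pytest.fixture()
    def phases(self):
        t0 = pd.Timestamp("2017-05-01T00:00:00Z")
        return pd.DataFrame({
            "individual_id": "a",
            "state": ["resting", "active", "resting"],
            "t_start": [t0, t0 + pd.Timedelta(hours=1), t0 + pd.Timedelta(hours=2)],
            "t_end": [t0 + pd.Timedelta(hours=1), t0 + pd.Timedelta(hours=2),
                      t0 + pd.Timedelta(hours=3)],
        })

    def step_at(self, start_min, end_min):
        t0 = pd.Timestamp("2017-05-01T00:00:00Z")
        return pd.DataFrame({
            "individual_id": ["a"],
            "t_start": [t0 + pd.Timedelta(minutes=start_min)],
            "t_end": [t0 + pd.Timedelta(minutes=end_min)],
        })

    @pytest.mark.parametrize("start,end,expected", [
        (70, 75, "active"),       # both endpoints inside the active hour
        (55, 65, "resting"),      # mixed start resting / end active
        (115, 125, "resting"),    # mixed start active / end resting
        (10, 15, "resting"),      # both resting
    ])
    def test_both_endpoints_rule(self, phases, start, end, expected):
        out = label_step_activity(self.step_at(start, end), phases)
        assert out["activity"].iloc[0] == expected

    def test_step_outside_coverage_is_unknown(self, phases):
        out = label_step_activity(self.step_at(500, 505), phases)
        assert out["activity"].iloc[0] == "unknown"

    def test_agreement_with_truth_on_separated_amplitudes(self, small_sim,
                                                          run_config):
        """Signal/noise 10 between active and resting dynamic amplitudes."""
        from stepflow import steps as st
        dba = smooth_activity(compute_dba(small_sim["acc"]),
                              run_config.smoothing_window)
        phases = classify_phases(dba, run_config)
        fixes = st.filter_bursts(st.segment_bursts(small_sim["fixes"],
                                                   run_config), 50)
        steps = label_step_activity(st.build_steps(fixes), phases)
        merged = steps.merge(small_sim["truth"], on=["individual_id", "t_start"])
        known = merged[merged["activity"] != "unknown"]
        agreement = (known["activity"] == known["true_activity"]).mean()
        assert agreement >= 0.95
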