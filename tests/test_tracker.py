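import numpy as np
import pytest

import dyadtiming as dt
from dyadtiming.score import IOIClass
from dyadtiming.tracker import ClassState, TrackerConfig, _enforce_order

from conftest import make_series, run_sim_trial


def states_from_means(means_s, sd=0.05):
    return [
        ClassState(label, float(np.log2(m)), sd)
        for label, m in zip(IOIClass, means_s)
    ]


class TestInitClasses:
    def test_separated_clusters_recovered_exactly(self):
        durations = [0.25] * 8 + [0.5] * 6 + [0.75] * 4
        rng = np.random.default_rng(0)
        durations = list(rng.permutation(durations))
        states = dt.init_classes(make_series(durations))
        assert [s.label for s in states] == list(IOIClass)
        assert [s.predicted_duration for s in states] == pytest.approx([0.25, 0.5, 0.75])

    def test_degenerate_falls_back_to_ratio_centers(self):
        with pytest.warns(UserWarning, match="degenerate"):
            states = dt.init_classes(make_series([0.5] * 10))
        assert [s.predicted_duration for s in states] == pytest.approx([0.25, 0.5, 0.75])

    def test_jittered_clusters_recovered_within_5pct(self):
        nominal = {IOIClass.SHORT: 0.25, IOIClass.MID: 0.5, IOIClass.LONG: 0.75}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            classes = [IOIClass((i % 3) + 1) for i in range(30)]
            durations = [
                nominal[c] * 2 ** rng.normal(0, 0.03) for c in classes
            ]
            states = dt.init_classes(make_series(durations))
            for s in states:
                assert s.predicted_duration == pytest.approx(nominal[s.label], rel=0.05)

    def test_too_few_iois_rejected(self):
        with pytest.raises(dt.InsufficientDataError):
            dt.init_classes(make_series([0.5, 0.5]))


class TestClassifyIOI:
    @pytest.mark.parametrize(
        "duration, expected",
        [
            (0.5, IOIClass.MID),
            # verified: |log2(.62/.75)| = 0.275 < |log2(.62/.5)| = 0.310
            (0.62, IOIClass.LONG),
            (0.2, IOIClass.SHORT),
            (3.0, IOIClass.LONG),
        ],
    )
    def test_nearest_log2_mean(self, duration, expected):
        assert dt.classify_ioi(duration, states_from_means([0.25, 0.5, 0.75])) == expected

    def test_tie_breaks_to_shorter_class(self):
        midpoint = float(np.sqrt(0.25 * 0.5))  # exact log2 midpoint of S and M
        assert dt.classify_ioi(midpoint, states_from_means([0.25, 0.5, 0.75])) == IOIClass.SHORT

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(dt.InvalidInputError):
            dt.classify_ioi(0.0, states_from_means([0.25, 0.5, 0.75]))


class TestUpdateClass:
    def test_window_mean_equal_prior_is_fixed_point(self):
        cfg = TrackerConfig()
        state = ClassState(IOIClass.MID, -1.0, 0.05)
        out = dt.update_class(state, -1.0, now=20.0, cfg=cfg)
        assert out.mu == pytest.approx(-1.0)

    def test_single_value_moves_one_sixth(self):
        cfg = TrackerConfig(prior_strength=5.0)
        state = ClassState(IOIClass.MID, 0.0, 0.05)
        out = dt.update_class(state, 0.6, now=20.0, cfg=cfg)
        assert out.mu == pytest.approx(0.1)  # 1/6 of the way toward 0.6

    def test_constant_inputs_converge_monotonically(self):
        cfg = TrackerConfig()
        state = ClassState(IOIClass.MID, 0.0, 0.05)
        target = 1.0
        gaps = []
        for step in range(40):
            state = dt.update_class(state, target, now=100.0 + 0.1 * step, cfg=cfg)
            gaps.append(abs(state.mu - target))
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.05

    def test_old_evidence_evicted(self):
        cfg = TrackerConfig(evidence_window_s=15.0)
        state = ClassState(IOIClass.MID, 0.0, 0.05, window=[(0.0, 5.0)])
        out = dt.update_class(state, 0.0, now=100.0, cfg=cfg)
        assert all(t >= 85.0 for t, _ in out.window)

    def test_sd_floor_enforced(self):
        cfg = TrackerConfig(sd_floor=0.02)
        state = ClassState(IOIClass.MID, 0.0, 0.5)
        out = dt.update_class(state, 0.0, now=1.0, cfg=cfg)
        assert out.sd == pytest.approx(0.02)


class TestPredictionError:
    @pytest.mark.parametrize(
        "duration, predicted, log2_err, ms_err",
        [
            (0.5, 0.5, 0.0, 0.0),
            (1.0, 0.5, 1.0, 500.0),
            (0.6, 0.5, np.log2(1.2), 100.0),
        ],
    )
    def test_values(self, duration, predicted, log2_err, ms_err):
        l2, ms = dt.prediction_error(duration, predicted)
        assert l2 == pytest.approx(log2_err)
        assert ms == pytest.approx(ms_err)

    def test_nonpositive_rejected(self):
        with pytest.raises(dt.InvalidInputError):
            dt.prediction_error(-0.1, 0.5)


class TestTrackPerformance:
    def test_noise_free_performance_has_zero_errors(self, clean_trial):
        summary, _, tracker = clean_trial
        assert summary.fluctuation_rmse_mean < 1e-9
        assert summary.collapse_pct == 0.0
        assert np.nanmax(np.abs(tracker.trace_.log2_error)) < 1e-9

    def test_linear_ramp_is_tracked(self):
        # jitter-free accelerating performance: adaptive priors follow the
        # ramp, so residuals stay small; frozen priors diverge.
        _, _, adaptive = run_sim_trial(
            seed=1, n_repeats=16, tempo_bpm=100.0, tempo_drift=("linear", 5.0),
            jitter_sigma_log2=0.0, p_omit=0.0, p_substitute=0.0, p_collapse=0.0,
        )
        assert np.nanmax(np.abs(adaptive.trace_.log2_error)) < 0.02
        _, _, frozen = run_sim_trial(
            seed=1, n_repeats=16, tempo_bpm=100.0, tempo_drift=("linear", 5.0),
            jitter_sigma_log2=0.0, p_omit=0.0, p_substitute=0.0, p_collapse=0.0,
            tracker_kwargs={"adapt": False},
        )
        assert np.nanmax(np.abs(frozen.trace_.log2_error)) > 0.05

    def test_single_gap_yields_single_collapse(self):
        summary, truth, _ = run_sim_trial(
            seed=4, jitter_sigma_log2=0.0, p_omit=0.0, p_substitute=0.0,
            n_collapse_events=1, gap_range_s=(3.0, 3.0),
        )
        assert truth.n_collapses == 1
        assert summary.n_collapses == 1

    def test_determinism(self):
        s1, _, t1 = run_sim_trial(seed=9)
        s2, _, t2 = run_sim_trial(seed=9)
        assert np.array_equal(t1.trace_.log2_error, t2.trace_.log2_error, equal_nan=True)
        assert s1.fluctuation_rmse_mean == s2.fluctuation_rmse_mean
        assert s1.narration_matching_pct == s2.narration_matching_pct

    def test_class_means_stay_ordered(self):
        _, _, tracker = run_sim_trial(seed=2, jitter_sigma_log2=0.08)
        mus = tracker.trace_.snapshot_mu
        assert np.all(mus[:, 0] < mus[:, 1])
        assert np.all(mus[:, 1] < mus[:, 2])

    def test_stationary_convergence_to_true_durations(self):
        # parameter recovery: with i.i.d. multiplicative noise each belief
        # settles near the true class log2-duration (n >= 500 IOIs)
        for seed in (0, 1, 2):
            _, _, tracker = run_sim_trial(
                seed=seed, n_repeats=32, jitter_sigma_log2=0.05,
                p_omit=0.0, p_substitute=0.0, p_collapse=0.0,
            )
            # 0.05 log2 units ~ 3.5% duration error, ~2.5 SE of the sparsest
            # class's trailing-window mean at jitter 0.05
            for state, nominal in zip(tracker.class_states_, (0.25, 0.5, 0.75)):
                assert abs(state.mu - np.log2(nominal)) < 0.05

    def test_collapses_never_enter_evidence_windows(self):
        _, _, tracker = run_sim_trial(
            seed=3, jitter_sigma_log2=0.0, p_omit=0.0, p_substitute=0.0,
            n_collapse_events=5, gap_range_s=(3.0, 6.0),
        )
        gap_log2 = np.log2(tracker.trace_.duration[tracker.trace_.is_collapse])
        for state in tracker.class_states_:
            window_values = [x for _, x in state.window]
            assert not set(np.round(gap_log2, 12)) & set(np.round(window_values, 12))

    def test_enforce_order_resorts_swapped_states(self):
        swapped = [
            ClassState(IOIClass.SHORT, np.log2(0.75), 0.05),
            ClassState(IOIClass.MID, np.log2(0.5), 0.05),
            ClassState(IOIClass.LONG, np.log2(0.25), 0.05),
        ]
        with pytest.warns(UserWarning, match="ordering"):
            fixed = _enforce_order(swapped)
        mus = [s.mu for s in sorted(fixed, key=lambda s: s.label)]
        assert mus == sorted(mus)

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        tracker = dt.IOIClassTracker(prior_strength=7.0)
        assert tracker.get_params()["prior_strength"] == 7.0
        cloned = clone(tracker)
        assert cloned.get_params() == tracker.get_params()
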