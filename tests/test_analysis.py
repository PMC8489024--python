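"""Analysis: blink interpolation, z-scoring, ERTs, locomotion, FDR, MAE."""

import numpy as np
import pytest

from pupilkit.analysis import (
    BlinkEpoch,
    TrialMatrix,
    bh_adjust,
    blink_epochs,
    deblink,
    event_align,
    locomotion_state,
    pointwise_significance,
    trace_mae,
    zscore_trials,
)
from pupilkit.trace import PupilTrace


def make_trace(areas, blink_probs=None, fps=30.0):
    n = len(areas)
    if blink_probs is None:
        blink_probs = np.zeros(n)
    return PupilTrace(
        fps=fps,
        frame=np.arange(n),
        time_s=np.arange(n) / fps,
        area_px=np.asarray(areas, dtype=float),
        pupil_x=np.full(n, 64.0),
        pupil_y=np.full(n, 64.0),
        eye_prob=np.ones(n),
        blink_prob=np.asarray(blink_probs, dtype=float),
    )


class TestBlinkEpochs:
    def test_no_blinks(self):
        assert blink_epochs(make_trace(np.ones(5))) == []

    def test_single_run_half_open(self):
        trace = make_trace(np.ones(5), [0, 0, 0.9, 0.9, 0])
        assert blink_epochs(trace, cutoff=0.5) == [BlinkEpoch(2, 4)]

    def test_merge_gap(self):
        probs = np.zeros(10)
        probs[2:4] = 0.9
        probs[5:7] = 0.9
        trace = make_trace(np.ones(10), probs)
        assert blink_epochs(trace, cutoff=0.5, merge_gap=2) == [BlinkEpoch(2, 7)]
        assert blink_epochs(trace, cutoff=0.5, merge_gap=1) == [BlinkEpoch(2, 4), BlinkEpoch(5, 7)]


class TestDeblink:
    def test_flat_neighbors(self):
        trace = make_trace([10, 10, 99, 99, 10], fps=2.0)  # window = 1, no filtering
        out = deblink(trace, [BlinkEpoch(2, 4)])
        np.testing.assert_allclose(out.area_px, 10.0)

    def test_linear_fill(self):
        trace = make_trace([0, 99, 99, 30], fps=2.0)
        out = deblink(trace, [BlinkEpoch(1, 3)])
        np.testing.assert_allclose(out.area_px, [0, 10, 20, 30])

    def test_median_window_from_fps(self):
        # 30 fps -> round(0.5*30) = 15, already odd
        trace = make_trace(np.arange(60.0), fps=30.0)
        out = deblink(trace, [])
        # linear ramp is invariant under median filtering away from edges
        np.testing.assert_allclose(out.area_px[8:-8], trace.area_px[8:-8])

    def test_even_window_forced_odd(self):
        # fps 8 -> round(4) = 4 -> forced to 5; an impulse of width <= 2 is erased
        areas = np.full(40, 10.0)
        areas[20] = 100.0
        out = deblink(make_trace(areas, fps=8.0), [])
        assert out.area_px[20] == 10.0

    def test_edge_epoch_held_at_nearest(self):
        trace = make_trace([99, 99, 5, 5], fps=2.0)
        out = deblink(trace, [BlinkEpoch(0, 2)])
        np.testing.assert_allclose(out.area_px, 5.0)

    def test_all_blink_rejected(self):
        with pytest.raises(ValueError):
            deblink(make_trace([1, 2, 3]), [BlinkEpoch(0, 3)])

    def test_identity_with_no_epochs_and_unit_window(self):
        trace = make_trace(np.random.default_rng(0).uniform(10, 20, 30), fps=1.0)
        out = deblink(trace, [])  # round(0.5*1)=0 -> forced 1 -> no filtering
        np.testing.assert_array_equal(out.area_px, trace.area_px)


class TestZscore:
    def matrix(self, values, fps=10.0):
        values = np.atleast_2d(values)
        t = (np.arange(values.shape[1]) - values.shape[1] // 2) / fps
        return TrialMatrix(values=values, time_s=t, baseline=(t[0], 0.0))

    def test_formula(self):
        # baseline mean 100, SD 10 -> a post-onset sample of 120 maps to z = 2
        base = np.array([90.0, 100.0, 110.0])  # mean 100, sample SD 10
        m = self.matrix(np.concatenate([base, [120.0, 120.0, 120.0]]))
        z = zscore_trials(m)
        post = z.time_s >= 0
        np.testing.assert_allclose(z.values[0, post], 2.0)

    def test_constant_trial_at_baseline_mean_is_zero(self):
        m = self.matrix(np.array([[5.0, 6.0, 4.0, 5.0, 5.0, 5.0]]))
        z = zscore_trials(m)
        assert abs(z.values[0, -1]) < 1e-12

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100, 15, size=(6, 40))
        m = self.matrix(vals)
        z = zscore_trials(m)
        cols = m.baseline_cols()
        for i in range(6):
            mu = vals[i, cols].mean()
            sd = np.sqrt(((vals[i, cols] - mu) ** 2).sum() / (cols.sum() - 1))
            np.testing.assert_allclose(z.values[i], (vals[i] - mu) / sd, atol=1e-12)

    def test_baseline_normalized_after_transform(self):
        rng = np.random.default_rng(1)
        m = self.matrix(rng.normal(50, 5, size=(4, 30)))
        z = zscore_trials(m)
        cols = z.baseline_cols()
        base = z.values[:, cols]
        assert np.abs(base.mean(axis=1)).max() < 1e-10
        assert np.abs(base.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_zero_sd_trial_excluded_with_warning(self):
        vals = np.vstack([np.ones(10), np.random.default_rng(2).normal(size=10)])
        m = self.matrix(vals)
        with pytest.warns(UserWarning):
            z = zscore_trials(m)
        assert z.values.shape[0] == 1


class TestEventAlign:
    def test_15s_window_at_30fps_is_450_samples(self):
        trace = make_trace(np.random.default_rng(0).uniform(size=1200), fps=30.0)
        m = event_align(trace, [20.0], window=(7.5, 7.5))
        assert m.values.shape == (1, 450)

    def test_underflowing_events_dropped_with_warning(self):
        trace = make_trace(np.ones(600), fps=30.0)
        with pytest.warns(UserWarning):
            m = event_align(trace, [1.0, 10.0], window=(7.5, 2.5))
        assert m.values.shape[0] == 1

    def test_no_valid_events_rejected(self):
        trace = make_trace(np.ones(30), fps=30.0)
        with pytest.raises(ValueError):
            event_align(trace, [0.1], window=(7.5, 7.5))

    def test_rows_sampled_on_frame_grid(self):
        areas = np.arange(100, dtype=float)
        trace = make_trace(areas, fps=10.0)
        m = event_align(trace, [5.0], window=(1.0, 1.0))
        np.testing.assert_array_equal(m.values[0], areas[40:60])


class TestLocomotion:
    def test_boundary_at_ten_percent(self):
        v = np.array([2.0, 1.99, 20.0])
        state = locomotion_state(v)
        assert state.tolist() == [True, False, True]

    def test_constant_positive_all_moving(self):
        assert locomotion_state(np.full(5, 3.3)).all()

    def test_all_zero_all_stationary(self):
        assert not locomotion_state(np.zeros(5)).any()

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 10, 50)
        np.testing.assert_array_equal(locomotion_state(v), locomotion_state(v * 7.3))


class TestSignificance:
    def test_bh_worked_example(self):
        # hand computation: sorted p * n/rank, cumulative min from the largest
        p = np.array([0.005, 0.009, 0.05, 0.1, 0.9])
        expected = [0.0225, 0.0225, 0.25 / 3, 0.125, 0.9]
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_single_p_value_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_fewer_than_three_trials_rejected(self):
        m = TrialMatrix(values=np.ones((2, 10)), time_s=np.arange(10) - 5.0, baseline=(-5.0, 0.0))
        with pytest.raises(ValueError):
            pointwise_significance(m)

    def test_injected_effect_detected_null_not(self):
        rng = np.random.default_rng(0)
        n_trials, n_time = 12, 40
        t = (np.arange(n_time) - 20) / 10.0
        vals = rng.normal(0, 1, (n_trials, n_time))
        vals[:, 30:34] += 5.0  # 5 SD effect
        m = TrialMatrix(values=vals, time_s=t, baseline=(-2.0, 0.0))
        times, p_adj, sig = pointwise_significance(m)
        post = np.nonzero(t >= 0)[0]
        hit = {i for i, tp in enumerate(post) if sig[i]}
        assert {i for i, tp in enumerate(post) if tp in range(30, 34)} <= hit

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(42)
        rates = []
        for _ in range(100):
            vals = rng.normal(size=(8, 30))
            m = TrialMatrix(values=vals, time_s=(np.arange(30) - 15.0) / 10.0,
                            baseline=(-1.5, 0.0))
            _, _, sig = pointwise_significance(m)
            rates.append(sig.mean())
        assert np.mean(rates) <= 0.05


class TestTraceMae:
    def test_identical_traces_zero(self):
        x = np.sin(np.linspace(0, 5, 100))
        assert trace_mae(x, 10.0, x, 10.0) == 0.0

    def test_mirrored_trace_brute_force(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=50)
        b = -a
        # after [-1, 1] normalization b_hat = -a_hat, so MAE = mean |2 a_hat|
        a_hat = 2 * (a - a.min()) / (a.max() - a.min()) - 1
        expected = np.abs(2 * a_hat).mean()
        assert trace_mae(a, 10.0, b, 10.0) == pytest.approx(expected)

    def test_subsampled_sinusoid_small_interpolation_error(self):
        # 0.1 Hz sinusoid: 15 fps samples linearly upsampled to 1000 fps
        t_hi = np.arange(0, 10, 1 / 1000)
        hi = np.sin(2 * np.pi * 0.1 * t_hi)
        t_lo = np.arange(0, 10, 1 / 15)
        lo = np.sin(2 * np.pi * 0.1 * t_lo)
        assert trace_mae(lo, 15.0, hi, 1000.0) <= 0.01

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            trace_mae(np.ones(10), 10.0, np.arange(10.0), 10.0)
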