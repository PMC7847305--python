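"""ΔF% computation, threshold calibration, responder calling, group stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisspulse import (
    DffTrace,
    ResponseThreshold,
    RoiTrace,
    TraceParams,
    calibrate_threshold,
    compare_groups,
    compute_dff,
    detect_response,
    qc_drift,
    simulate_dendron_traces,
    summarize_group,
)


def make_trace(raw, puff=(100.0, 190.0), rate=0.9, n0=20):
    raw = np.asarray(raw, dtype=float)
    t = np.arange(len(raw)) / rate
    return RoiTrace(roi_id="r", times=t, raw_f=raw, frame_rate=rate,
                    puff_window=puff, baseline_frames=n0)


def flat_dff(dff_values, times=None, puff=(100.0, 190.0)):
    v = np.asarray(dff_values, dtype=float)
    t = np.arange(len(v)) / 0.9 if times is None else times
    return DffTrace(roi_id="r", times=t, dff=v, drift=0.0, qc_pass=True, puff_window=puff)


class TestComputeDff:
    def test_constant_trace_reads_zero(self):
        d = compute_dff(make_trace(np.full(450, 500.0)))
        np.testing.assert_allclose(d.dff, 0.0)
        assert d.qc_pass

    def test_step_to_double_reads_100_percent(self):
        raw = np.full(450, 300.0)
        raw[200:230] = 600.0
        d = compute_dff(make_trace(raw))
        assert d.dff[210] == pytest.approx(100.0)

    def test_planted_sustained_rise_recovered(self):
        p = TraceParams(n_rois=5, response_fraction=1.0, noise_sd=1.0, seed=3)
        traces, _ = simulate_dendron_traces(p)
        for t in traces:
            d = compute_dff(t)
            assert d.dff.max() == pytest.approx(35.0, abs=5.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            compute_dff(make_trace(np.zeros(450)))

    @given(gain=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(5)
        raw = 400.0 * (1 + 0.1 * rng.random(450))
        d1 = compute_dff(make_trace(raw))
        d2 = compute_dff(make_trace(gain * raw))
        np.testing.assert_allclose(d1.dff, d2.dff, rtol=1e-9, atol=1e-9)


class TestQcDrift:
    def test_zero_drift_passes(self):
        assert qc_drift(flat_dff(np.zeros(450)))

    def test_drift_exactly_at_limit_fails(self):
        d = flat_dff(np.zeros(450))
        d.drift = 5.0
        assert not qc_drift(d)


class TestCalibrateThreshold:
    def test_printed_control_stats_give_5p5(self):
        # sample mean 4.5, sample SD 0.5 -> threshold 4.5 + 2*0.5 = 5.5 exactly
        thr = calibrate_threshold([4.0, 4.5, 5.0])
        assert thr.control_mean == pytest.approx(4.5)
        assert thr.control_sd == pytest.approx(0.5)
        assert thr.threshold == pytest.approx(5.5)

    def test_all_zero_controls(self):
        assert calibrate_threshold([0.0, 0.0, 0.0]).threshold == 0.0

    def test_monte_carlo_normal_controls(self):
        rng = np.random.default_rng(42)
        thr = calibrate_threshold(rng.normal(4.5, 0.5, size=1000))
        assert thr.threshold == pytest.approx(5.5, abs=0.1)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            calibrate_threshold([4.5])

    @given(shift=st.floats(-10, 10), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_and_scale_equivariance(self, shift, scale):
        base = np.array([3.1, 4.0, 4.6, 5.2, 6.0])
        t0 = calibrate_threshold(base)
        t_shift = calibrate_threshold(base + shift)
        t_scale = calibrate_threshold(base * scale)
        assert t_shift.threshold == pytest.approx(t0.threshold + shift, rel=1e-9, abs=1e-9)
        assert t_scale.threshold - t_scale.control_mean == pytest.approx(
            scale * (t0.threshold - t0.control_mean), rel=1e-9, abs=1e-9
        )


class TestDetectResponse:
    THR = ResponseThreshold(control_mean=4.5, control_sd=0.5)

    def test_planted_sustained_response_is_responder(self):
        p = TraceParams(n_rois=3, response_fraction=1.0, noise_sd=1.0, seed=9)
        traces, _ = simulate_dendron_traces(p)
        for t in traces:
            call = detect_response(compute_dff(t), self.THR)
            assert call.responder
            assert call.peak_dff > 0

    def test_bump_confined_to_puff_fails_duration(self):
        t = np.arange(450) / 0.9
        dff = np.where((t >= 100) & (t <= 190), 6.0, 0.0)
        call = detect_response(flat_dff(dff, times=t), self.THR)
        assert call.exceeds_threshold
        assert not call.outlasts_puff
        assert not call.responder

    def test_flat_trace_is_non_responder(self):
        call = detect_response(flat_dff(np.zeros(450)), self.THR)
        assert not call.responder

    def test_decrease_is_eligible_with_sign_retained(self):
        t = np.arange(450) / 0.9
        dff = np.where(t >= 100, -20.0, 0.0)
        call = detect_response(flat_dff(dff, times=t), self.THR)
        assert call.responder
        assert call.peak_dff == pytest.approx(-20.0)


class TestSummarizeGroup:
    def test_identical_traces_have_zero_ci_width(self):
        d = flat_dff(np.linspace(0, 10, 450))
        s = summarize_group([d, d, d], [])
        np.testing.assert_allclose(s.ci_upper - s.ci_lower, 0.0, atol=1e-12)

    def test_auc_of_rectangle(self):
        t = np.arange(0.0, 200.0 + 1e-9, 1.0)
        dff = np.where((t >= 50) & (t < 150), 10.0, 0.0)
        d = DffTrace("r", t, dff, 0.0, True, (50.0, 150.0))
        s = summarize_group([d], [])
        assert s.auc == pytest.approx(1000.0, rel=0.02)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            summarize_group([], [])


class TestCompareGroups:
    def test_identical_unpaired_samples_no_evidence(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.5

    def test_separated_normals_highly_significant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 50), rng.normal(2, 1, 50)
        res = compare_groups(a, b)
        assert res.test == "mann-whitney"
        assert res.p_value < 0.001

    def test_paired_self_comparison_flagged_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        res = compare_groups(a, a, design="paired")
        assert res.degenerate
        assert res.p_value == 1.0

    def test_kgroup_kruskal_with_dunn_posthoc(self):
        rng = np.random.default_rng(1)
        g = [rng.normal(m, 1, 30) for m in (0, 0, 3)]
        res = compare_groups(*g)
        assert res.test == "kruskal-wallis"
        assert res.p_value < 0.001
        posthoc = {(i, j): p for i, j, p in res.posthoc}
        assert posthoc[(0, 1)] > 0.05
        assert posthoc[(0, 2)] < 0.01

    def test_paired_kgroup_uses_friedman(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 25)
        res = compare_groups(base, base + rng.normal(1, 0.3, 25),
                             base + rng.normal(2, 0.3, 25), design="paired")
        assert res.test == "friedman"
        assert res.p_value < 0.01
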