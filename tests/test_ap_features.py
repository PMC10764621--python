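"""Feature-extraction correctness against analytic oracles and generator
ground truth."""

import numpy as np
import pytest

from sanpace import APConfig, APGroundTruth, VoltageTrace, generate_ap_train
from sanpace.ap_features import (
    APCycle,
    compute_apd50,
    compute_eddr,
    compute_top,
    cycles_to_frame,
    detect_aps,
    estimate_dvdt,
    extract_cycles,
    segment_cycles,
    summarize_window,
)

FS = 10_000.0
DT = 1.0 / FS


def _trace(v):
    return VoltageTrace(sampling_interval=DT, samples=np.asarray(v, float))


class TestEstimateDvdt:
    def test_linear_ramp_exact(self):
        t_ms = np.arange(30000) * DT * 1000.0
        tr = _trace(-60.0 + 0.1 * t_ms)
        d = estimate_dvdt(tr)
        assert np.max(np.abs(d[50:-50] - 0.1)) < 1e-6

    def test_sine_peak_matches_closed_form(self):
        f, amp = 5.0, 10.0
        t = np.arange(int(2 * FS)) * DT
        d = estimate_dvdt(_trace(amp * np.sin(2 * np.pi * f * t)))
        expected = 2 * np.pi * f * amp / 1000.0  # mV/ms
        assert d.max() == pytest.approx(expected, rel=1e-3)

    def test_noisy_ramp_mean_within_5pct(self, rng):
        t_ms = np.arange(10000) * DT * 1000.0
        v = -60.0 + 0.1 * t_ms + rng.normal(0, 0.2, t_ms.size)
        d = estimate_dvdt(_trace(v))
        assert np.mean(d[100:-100]) == pytest.approx(0.1, rel=0.05)

    def test_window_longer_than_trace_errors(self):
        tr = _trace(np.zeros(100))
        with pytest.raises(ValueError, match="window"):
            estimate_dvdt(tr, APConfig(smoothing_window_ms=1000.0))


class TestDetectAps:
    def test_anchor_count_matches_cycle_count(self):
        gt = APGroundTruth(cycle_length_ms=200.0, noise_sd_mV=0.0)
        tr, _ = generate_ap_train(gt, duration_s=10.0)
        anchors = detect_aps(tr, estimate_dvdt(tr))
        assert abs(anchors.size - 50) <= 1

    def test_flat_trace_empty_with_warning(self):
        tr = _trace(np.full(30000, -60.0))
        with pytest.warns(UserWarning, match="no action potentials"):
            anchors = detect_aps(tr, estimate_dvdt(tr))
        assert anchors.size == 0

    def test_one_doubled_amplitude_ap_does_not_mask_others(self):
        gt = APGroundTruth(noise_sd_mV=0.0)
        tr, truth = generate_ap_train(gt, duration_s=10.0)
        base = detect_aps(tr, estimate_dvdt(tr)).size
        # stretch one cycle's voltage excursion (and hence its dV/dt) 2x
        v = tr.samples.copy()
        i0 = int(truth["start_time_s"].iloc[10] * FS)
        i1 = int(truth["start_time_s"].iloc[11] * FS)
        v[i0:i1] = gt.mdp_mV + 2.0 * (v[i0:i1] - gt.mdp_mV)
        tr2 = VoltageTrace(sampling_interval=DT, samples=v)
        assert detect_aps(tr2, estimate_dvdt(tr2)).size == base


class TestSegmentCycles:
    def test_n_anchors_give_at_most_n_minus_2_cycles(self, noiseless_train):
        trace, _ = noiseless_train
        dvdt = estimate_dvdt(trace)
        anchors = detect_aps(trace, dvdt)[:5]
        cycles = segment_cycles(trace, dvdt, anchors)
        assert 0 < len(cycles) <= 4

    def test_noiseless_mdp_recovered(self, noiseless_gt, noiseless_train):
        trace, _ = noiseless_train
        dvdt = estimate_dvdt(trace)
        cycles = segment_cycles(trace, dvdt, detect_aps(trace, dvdt))
        for c in cycles:
            assert c.mdp_mV == pytest.approx(noiseless_gt.mdp_mV, abs=0.5)

    def test_non_monotonic_anchors_error(self, noiseless_train):
        trace, _ = noiseless_train
        dvdt = estimate_dvdt(trace)
        anchors = detect_aps(trace, dvdt)
        with pytest.raises(ValueError, match="increasing"):
            segment_cycles(trace, dvdt, anchors[::-1])
        with pytest.raises(ValueError, match="anchors"):
            segment_cycles(trace, dvdt, anchors[:2])


class TestComputeTop:
    def test_fraction_one_gives_dvdt_max_time(self, noiseless_train):
        trace, _ = noiseless_train
        cfg = APConfig(top_fraction=1.0)
        cycles = extract_cycles(trace, cfg)
        for c in cycles:
            assert c.top_time_s == pytest.approx(c.dvdt_max_time_s, abs=DT)

    def test_matches_generator_operational_top(self, noiseless_train):
        trace, truth = noiseless_train
        cycles = [c for c in extract_cycles(trace) if c.valid]
        assert all(abs(c.top_mV - truth["top_op_mV"].iloc[0]) < 0.5
                   for c in cycles)

    def test_no_upstroke_flagged_invalid(self):
        # pure diastolic ramp: dV/dt never dips below 10% of its own max
        t_ms = np.arange(5000) * DT * 1000.0
        tr = _trace(-60.0 + 0.1 * t_ms)
        dvdt = estimate_dvdt(tr)
        cyc = APCycle(mdp_time_s=0.0, mdp_mV=-60.0,
                      peak_time_s=4999 * DT, peak_mV=tr.samples[-1],
                      next_mdp_time_s=4999 * DT, dvdt_max_mV_per_ms=0.1,
                      dvdt_max_time_s=2500 * DT,
                      _idx={"mdp": 0, "anchor": 2500, "peak": 4999,
                            "next_mdp": 4999})
        compute_top(cyc, tr, dvdt)
        assert not cyc.valid and cyc.invalid_reason == "no_top_crossing"


class TestComputeEddr:
    def test_linear_ramp_exact(self, noiseless_gt, noiseless_train):
        trace, _ = noiseless_train
        cycles = [c for c in extract_cycles(trace) if c.valid]
        for c in cycles:
            assert c.eddr_mV_per_ms == pytest.approx(
                noiseless_gt.edd_slope_mV_per_ms, rel=1e-6)

    def test_exponential_diastole_matches_analytic_mean_slope(self):
        """V(t) = MDP + (TOP-MDP)(1 - e^(-t/tau)): the mean dV/dt over
        [0.1 D, 0.5 D] equals (V(0.5 D) - V(0.1 D)) / (0.4 D)."""
        mdp, top, tau_ms, d_ms = -60.0, -40.0, 80.0, 120.0
        t_ms = np.arange(int(d_ms / 1000.0 * FS) + 1) * DT * 1000.0
        volt = mdp + (top - mdp) * (1.0 - np.exp(-t_ms / tau_ms))
        tr = _trace(volt)
        dvdt = estimate_dvdt(tr)
        n = t_ms.size - 1
        cyc = APCycle(mdp_time_s=0.0, mdp_mV=mdp,
                      peak_time_s=n * DT, peak_mV=volt[-1],
                      next_mdp_time_s=n * DT, dvdt_max_mV_per_ms=1.0,
                      dvdt_max_time_s=n * DT, top_time_s=d_ms / 1000.0,
                      top_mV=volt[-1],
                      _idx={"mdp": 0, "anchor": n, "peak": n,
                            "next_mdp": n})
        compute_eddr(cyc, tr, dvdt)

        def v_of(t):  # analytic voltage, t in ms
            return mdp + (top - mdp) * (1.0 - np.exp(-t / tau_ms))

        expected = (v_of(0.5 * d_ms) - v_of(0.1 * d_ms)) / (0.4 * d_ms)
        assert cyc.eddr_mV_per_ms == pytest.approx(expected, rel=1e-3)

    def test_drug_scaled_ratio(self):
        from sanpace import DrugEffectSpec
        gt = APGroundTruth(noise_sd_mV=0.0)
        drug = DrugEffectSpec(onset_time_s=0.0, effect_fraction=0.25,
                              onset_tau_s=1e-9)
        tr_b, _ = generate_ap_train(gt, duration_s=8.0)
        tr_d, _ = generate_ap_train(gt, drug, duration_s=8.0)
        e_b = summarize_window(extract_cycles(tr_b)).eddr_mV_per_ms
        e_d = summarize_window(extract_cycles(tr_d)).eddr_mV_per_ms
        assert e_d / e_b == pytest.approx(0.75, rel=0.05)

    def test_voltage_interval_interpretation_close_on_linear_ramp(
            self, noiseless_train):
        # on a linear diastole both interpretations give the same span
        trace, _ = noiseless_train
        cfg = APConfig(eddr_interval="voltage")
        cycles = [c for c in extract_cycles(trace, cfg) if c.valid]
        assert cycles
        for c in cycles[:5]:
            assert c.eddr_mV_per_ms == pytest.approx(0.15, rel=0.05)


class TestComputeApd50:
    def test_generator_apd50_recovered(self, noiseless_gt, noiseless_train):
        trace, _ = noiseless_train
        cycles = [c for c in extract_cycles(trace) if c.valid]
        for c in cycles:
            assert c.apd50_ms == pytest.approx(noiseless_gt.apd50_ms,
                                               abs=1.0)

    def test_symmetric_triangle_gives_half_base_width(self):
        w_ms = 40.0
        half = int(w_ms / 2 / 1000.0 * FS)
        up = np.linspace(-60.0, 20.0, half, endpoint=False)
        down = np.linspace(20.0, -60.0, half + 1)
        v = np.concatenate([up, down])
        tr = _trace(v)
        n = v.size - 1
        cyc = APCycle(mdp_time_s=0.0, mdp_mV=-60.0,
                      peak_time_s=half * DT, peak_mV=20.0,
                      next_mdp_time_s=n * DT, dvdt_max_mV_per_ms=1.0,
                      dvdt_max_time_s=0.0,
                      _idx={"mdp": 0, "anchor": half // 2, "peak": half,
                            "next_mdp": n})
        compute_apd50(cyc, tr)
        assert cyc.apd50_ms == pytest.approx(w_ms / 2.0, abs=2 * DT * 1000)

    def test_zero_amplitude_invalid(self):
        tr = _trace(np.full(1000, -60.0))
        cyc = APCycle(mdp_time_s=0.0, mdp_mV=-60.0, peak_time_s=0.05,
                      peak_mV=-60.0, next_mdp_time_s=0.09,
                      dvdt_max_mV_per_ms=0.0, dvdt_max_time_s=0.02,
                      _idx={"mdp": 0, "anchor": 500, "peak": 500,
                            "next_mdp": 999})
        compute_apd50(cyc, tr)
        assert not cyc.valid and cyc.invalid_reason == "zero_amplitude"


class TestSummarizeWindow:
    def test_firing_rate_from_mean_cycle_length(self):
        gt = APGroundTruth(cycle_length_ms=200.0, noise_sd_mV=0.0)
        tr, _ = generate_ap_train(gt, duration_s=10.0)
        summary = summarize_window(extract_cycles(tr), window="baseline")
        assert summary.firing_rate_bpm == pytest.approx(300.0, rel=1e-6)

    def test_invalid_cycles_excluded_and_counted(self, noiseless_train):
        trace, _ = noiseless_train
        cycles = extract_cycles(trace)
        for c in cycles[:3]:
            c.invalidate("test")
        summary = summarize_window(cycles)
        assert summary.n_invalid == 3
        assert summary.n_cycles == len(cycles) - 3

    def test_too_few_valid_cycles_names_window(self, noiseless_train):
        trace, _ = noiseless_train
        cycles = extract_cycles(trace)[:4]
        for c in cycles[:2]:
            c.invalidate("test")
        with pytest.raises(ValueError, match="drug"):
            summarize_window(cycles, window="drug")

    def test_full_parameter_recovery_noiseless(self, noiseless_train):
        trace, truth = noiseless_train
        s = summarize_window(extract_cycles(trace))
        t0 = truth.iloc[0]
        assert s.firing_rate_bpm == pytest.approx(t0.rate_bpm, rel=0.02)
        assert s.amplitude_mV == pytest.approx(t0.amplitude_mV, rel=0.02)
        assert s.apd50_ms == pytest.approx(t0.apd50_ms, rel=0.02)
        assert s.mdp_mV == pytest.approx(t0.mdp_mV, rel=0.02)
        assert s.top_mV == pytest.approx(t0.top_op_mV, rel=0.02)
        assert s.eddr_mV_per_ms == pytest.approx(t0.eddr_mV_per_ms,
                                                 rel=0.02)
        assert s.dvdt_max_mV_per_ms == pytest.approx(
            t0.dvdt_max_mV_per_ms, rel=0.02)


class TestInvariants:
    def test_ordering_invariant_on_noisy_train(self, noisy_train):
        trace, _ = noisy_train
        for c in extract_cycles(trace):
            if c.valid:
                assert c.mdp_mV <= c.top_mV <= c.peak_mV

    def test_cycles_frame_columns(self, noiseless_train):
        trace, _ = noiseless_train
        frame = cycles_to_frame(extract_cycles(trace))
        assert {"mdp_mV", "top_mV", "eddr_mV_per_ms", "apd50_ms",
                "valid"} <= set(frame.columns)
        assert frame["valid"].all()
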