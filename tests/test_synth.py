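"""Generator contracts: determinism, exact waveform landmarks, planted
structure, and rejection of infeasible parameter combinations."""

import numpy as np
import pytest

from sanpace import (
    APGroundTruth,
    DrugEffectSpec,
    GeneTableGroundTruth,
    RRGroundTruth,
    generate_ap_train,
    generate_gene_table,
    generate_rr_series,
)
from sanpace.synth import _make_geometry


class TestAPTrain:
    def test_noiseless_per_cycle_minimum_is_mdp(self, noiseless_gt,
                                                noiseless_train):
        trace, truth = noiseless_train
        cl_s = noiseless_gt.cycle_length_ms / 1000.0
        n_cycles = len(truth)
        assert n_cycles == int(np.floor(trace.duration_s / cl_s))
        # per-cycle minimum equals the specified MDP up to interpolation
        for t0 in truth["start_time_s"].to_numpy()[:5]:
            i0 = int(t0 / trace.sampling_interval)
            i1 = i0 + int(cl_s / trace.sampling_interval)
            assert np.min(trace.samples[i0:i1]) == pytest.approx(
                noiseless_gt.mdp_mV, abs=1e-6)

    def test_noiseless_extrema_match_spec(self, noiseless_gt,
                                          noiseless_train):
        trace, _ = noiseless_train
        assert trace.samples.min() == pytest.approx(noiseless_gt.mdp_mV,
                                                    abs=1e-6)
        # the sampling grid need not hit the exact peak time
        assert trace.samples.max() == pytest.approx(noiseless_gt.peak_mV,
                                                    abs=0.01)

    def test_same_seed_identical(self):
        gt = APGroundTruth(seed=5)
        t1, _ = generate_ap_train(gt, duration_s=3.0)
        t2, _ = generate_ap_train(gt, duration_s=3.0)
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_drug_steady_state_cycle_length_matches_geometry(self):
        """With an instantaneous-onset drug the cycle length follows the
        closed form CL' = T_dia / g + T_ap, where T_dia is the diastolic
        ramp duration and T_ap the (unchanged) AP-complex duration; the
        ramp-time closed form is itself verified by numerically
        integrating dV/dt = g * slope up to TOP - MDP."""
        gt = APGroundTruth(noise_sd_mV=0.0)
        g = 0.75
        drug = DrugEffectSpec(onset_time_s=0.0, effect_fraction=1.0 - g,
                              onset_tau_s=1e-9)
        _, truth = generate_ap_train(gt, drug, duration_s=10.0)
        t_dia = (gt.top_mV - gt.mdp_mV) / gt.edd_slope_mV_per_ms
        t_ap = gt.cycle_length_ms - t_dia
        expected_cl = t_dia / g + t_ap

        # independent oracle: integrate the scaled ramp numerically
        dt = 1e-3
        v, t_ramp = gt.mdp_mV, 0.0
        while v < gt.top_mV:
            v += g * gt.edd_slope_mV_per_ms * dt
            t_ramp += dt
        assert t_ramp == pytest.approx(t_dia / g, rel=1e-4)
        assert truth["cycle_length_ms"].iloc[-1] == pytest.approx(
            expected_cl, rel=1e-12)
        assert truth["eddr_mV_per_ms"].iloc[-1] == pytest.approx(
            g * gt.edd_slope_mV_per_ms)

    def test_washout_returns_cycle_length_to_baseline(self):
        gt = APGroundTruth(noise_sd_mV=0.0)
        drug = DrugEffectSpec(onset_time_s=2.0, effect_fraction=0.3,
                              onset_tau_s=0.5, washout_time_s=6.0,
                              washout_tau_s=0.5)
        _, truth = generate_ap_train(gt, drug, duration_s=20.0)
        assert truth["cycle_length_ms"].iloc[0] == gt.cycle_length_ms
        assert truth["cycle_length_ms"].max() > gt.cycle_length_ms * 1.05
        assert truth["cycle_length_ms"].iloc[-1] == pytest.approx(
            gt.cycle_length_ms, rel=1e-3)

    @pytest.mark.parametrize("bad", [
        dict(mdp_mV=-40.0, top_mV=-45.0),              # mdp above top
        dict(top_mV=20.0),                             # top above peak
        dict(edd_slope_mV_per_ms=-0.1),
        dict(upstroke_vmax_mV_per_ms=1.0),             # 10% vmax < slope
        dict(cycle_length_ms=120.0),                   # no room for AP
        dict(apd50_ms=300.0),                          # longer than cycle
    ])
    def test_infeasible_parameters_rejected(self, bad):
        gt = APGroundTruth(noise_sd_mV=0.0, **bad)
        with pytest.raises(ValueError, match="constraint|must"):
            generate_ap_train(gt, duration_s=5.0)

    def test_sampling_and_duration_preconditions(self):
        gt = APGroundTruth()
        with pytest.raises(ValueError, match="sampling_rate"):
            generate_ap_train(gt, duration_s=5.0, sampling_rate_hz=1000)
        with pytest.raises(ValueError, match="duration"):
            generate_ap_train(gt, duration_s=0.3)

    def test_operational_top_is_on_upstroke(self, noiseless_gt):
        geom = _make_geometry(
            noiseless_gt.mdp_mV, noiseless_gt.peak_mV, noiseless_gt.top_mV,
            noiseless_gt.edd_slope_mV_per_ms, noiseless_gt.cycle_length_ms,
            noiseless_gt.apd50_ms, noiseless_gt.upstroke_vmax_mV_per_ms)
        assert noiseless_gt.top_mV < geom.top_op_mV < noiseless_gt.peak_mV
        assert geom.t_dia < geom.top_op_t < geom.t0


class TestRRSeries:
    def test_zero_sd_gives_constant_series(self):
        rr = generate_rr_series(RRGroundTruth(sd_rr_ms=0.0,
                                              ar1_coefficient=0.0))
        assert np.ptp(rr.rr_ms) == 0.0

    def test_sample_sd_matches_parameter(self):
        # sd of the sample SD is approx sd / sqrt(2 (n-1))
        gt = RRGroundTruth(sd_rr_ms=5.0, ar1_coefficient=0.0,
                           duration_s=1000.0, seed=2)
        rr = generate_rr_series(gt)
        n = rr.n_beats
        assert n > 9000
        se = gt.sd_rr_ms / np.sqrt(2 * (n - 1))
        assert abs(np.std(rr.rr_ms, ddof=1) - gt.sd_rr_ms) < 3 * se

    def test_mean_matches_parameter(self):
        gt = RRGroundTruth(seed=8, duration_s=500.0)
        rr = generate_rr_series(gt)
        se = gt.sd_rr_ms / np.sqrt(rr.n_beats)
        # AR(1) inflates the SE of the mean by sqrt((1+phi)/(1-phi))
        infl = np.sqrt((1 + gt.ar1_coefficient) / (1 - gt.ar1_coefficient))
        assert abs(rr.rr_ms.mean() - gt.mean_rr_ms) < 3 * se * infl

    def test_planted_pauses_present(self):
        gt = RRGroundTruth(pause_count=3, pause_length_ms=300.0, seed=4)
        rr = generate_rr_series(gt)
        assert int(np.sum(rr.rr_ms >= 2.5 * gt.mean_rr_ms)) == 3

    def test_infeasible_sd_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_rr_series(RRGroundTruth(sd_rr_ms=60.0))

    def test_same_seed_identical(self):
        gt = RRGroundTruth(seed=9)
        r1, r2 = generate_rr_series(gt), generate_rr_series(gt)
        np.testing.assert_array_equal(r1.rr_ms, r2.rr_ms)


class TestGeneTable:
    def test_same_seed_identical(self):
        gt = GeneTableGroundTruth(seed=3, n_genes=200, n_receptors=20,
                                  n_enriched_a=3, n_enriched_b=4)
        v1, t1, _ = generate_gene_table(gt)
        v2, t2, _ = generate_gene_table(gt)
        assert v1.equals(v2) and t1.equals(t2)

    def test_planted_structure(self):
        gt = GeneTableGroundTruth(seed=1)
        values, truth, receptors = generate_gene_table(gt)
        assert len(values) == gt.n_genes
        counts = truth["true_class"].value_counts()
        assert counts["enriched_A"] == gt.n_enriched_a
        assert counts["enriched_B"] == gt.n_enriched_b
        # planted ids are receptors, and the planted sets are disjoint
        planted = truth[truth["true_class"].isin(["enriched_A",
                                                  "enriched_B"])]
        assert set(planted.index) <= set(receptors)

    def test_planted_shift_visible_in_group_means(self):
        gt = GeneTableGroundTruth(seed=6)
        values, truth, _ = generate_gene_table(gt)
        log2 = np.log2(values)
        a_cols = [c for c in values.columns if c.startswith("A_")]
        b_cols = [c for c in values.columns if c.startswith("B_")]
        diff = log2[a_cols].mean(axis=1) - log2[b_cols].mean(axis=1)
        planted_a = truth.index[truth["true_class"] == "enriched_A"]
        assert diff.loc[planted_a].min() > gt.log2_fc / 2

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            GeneTableGroundTruth(n_replicates=1)
        with pytest.raises(ValueError):
            GeneTableGroundTruth(n_receptors=10, n_enriched_a=8,
                                 n_enriched_b=8)
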