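import numpy as np
import pytest

from aifx.aif import AIFCurve, TimingPoints
from aifx.bolus import gamma_variate
from aifx.mbf import (MBFResult, TissueCurves, estimate_mbf, fermi_residue,
                      forward_tissue, threshold_sensitivity,
                      tissue_from_series)
from aifx.phantom import PhantomSpec, generate_phantom
from aifx.pipeline import run_pipeline


def _aif(t_end=40.0):
    t = np.arange(0, t_end, 0.5)
    return t, gamma_variate(t, 6.0, 100.0, 2.5, 1.8)


TP = TimingPoints(baseline_time=2.0, start_time=6.0, peak_time=10.5)


class TestFermiResidue:
    @pytest.mark.parametrize("k,tau", [(0.1, 0.0), (0.5, 3.0), (2.0, 1.0)])
    def test_initial_value_is_flow(self, k, tau):
        assert fermi_residue(0.0, 2.5, k, tau) == pytest.approx(2.5)

    def test_delta_like_limit(self):
        t = np.arange(0, 10, 0.5)
        r = fermi_residue(t, 1.0, 1000.0, 0.0)
        assert r[0] == pytest.approx(1.0)
        assert np.all(r[1:] < 1e-6)

    def test_monotone_non_increasing_for_random_parameters(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 60, 2000)
        for _ in range(50):
            r = fermi_residue(t, rng.uniform(0, 5), rng.uniform(0.01, 5),
                              rng.uniform(0, 10))
            assert np.all(np.diff(r) <= 1e-12)

    @pytest.mark.parametrize("F,k,tau", [(-1, 1, 1), (1, 0, 1), (1, 1, -1)])
    def test_invalid_parameters_rejected(self, F, k, tau):
        with pytest.raises(ValueError):
            fermi_residue(0.0, F, k, tau)


class TestEstimateMbf:
    def test_noiseless_forward_simulation_recovered(self):
        t, aif_v = _aif()
        tissue = forward_tissue(t, aif_v, 1.0, 0.5, 3.0)
        res = estimate_mbf(AIFCurve(times=t, values=aif_v),
                           TissueCurves(times=t, curves=tissue[None]), TP)
        assert res.flows[0] == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("F", [1.1, 3.2])
    def test_noisy_recovery_monte_carlo(self, F):
        t, aif_v = _aif()
        tissue0 = forward_tissue(t, aif_v, F, 0.15, 3.0)
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(50):
            noisy = tissue0 + rng.normal(0, 0.01 * tissue0.max(), tissue0.shape)
            res = estimate_mbf(AIFCurve(times=t, values=aif_v),
                               TissueCurves(times=t, curves=noisy[None]), TP)
            errs.append(abs(res.flows[0] - F) / F)
        assert np.median(errs) < 0.10

    def test_deconvolution_homogeneity(self):
        t, aif_v = _aif()
        tissue = forward_tissue(t, aif_v, 2.0, 0.3, 2.0)
        tis = TissueCurves(times=t, curves=tissue[None])
        f1 = estimate_mbf(AIFCurve(times=t, values=aif_v), tis, TP).flows[0]
        f2 = estimate_mbf(AIFCurve(times=t, values=3.0 * aif_v), tis, TP).flows[0]
        assert f1 / f2 == pytest.approx(3.0, rel=1e-3)

    def test_mismatched_grids_rejected(self):
        t, aif_v = _aif()
        with pytest.raises(ValueError):
            estimate_mbf(AIFCurve(times=t, values=aif_v),
                         TissueCurves(times=t[:-2], curves=aif_v[None, :-2]), TP)

    def test_result_is_deterministic(self):
        t, aif_v = _aif()
        tissue = forward_tissue(t, aif_v, 1.5, 0.2, 2.0) \
            + np.random.default_rng(3).normal(0, 0.05, len(t))
        tis = TissueCurves(times=t, curves=tissue[None])
        a = estimate_mbf(AIFCurve(times=t, values=aif_v), tis, TP)
        b = estimate_mbf(AIFCurve(times=t, values=aif_v), tis, TP)
        np.testing.assert_array_equal(a.flows, b.flows)


class TestTissueFromSeries:
    def test_six_equiangular_sectors_partition_annulus(self, default_phantom):
        series, truth = default_phantom
        tissue = tissue_from_series(series, truth.myo_mask,
                                    truth.spec.lv_center)
        assert tissue.n_sectors == 6
        union = tissue.sector_masks.any(axis=0)
        np.testing.assert_array_equal(union, truth.myo_mask)
        assert tissue.sector_masks.sum(axis=0).max() == 1

    def test_empty_mask_rejected(self, default_phantom):
        series, truth = default_phantom
        with pytest.raises(ValueError):
            tissue_from_series(series, np.zeros_like(truth.myo_mask),
                               truth.spec.lv_center)


class TestThresholdSensitivity:
    def _phantom_tissue(self, result, truth):
        t = result.aif.times
        aif_true = truth.spec.lv_curve(t)
        curves = np.stack([
            forward_tissue(t, aif_true, F, truth.spec.fermi_k, truth.spec.fermi_tau)
            for F in truth.flows])
        return TissueCurves(times=t, curves=curves)

    def test_homogeneous_lv_gives_identical_mbf_across_thresholds(self):
        spec = PhantomSpec(seed=21, noise_sigma=0.0, motion_amplitude_px=0.0,
                           papillary=())
        series, truth = generate_phantom(spec)
        result = run_pipeline(series)
        table = threshold_sensitivity(result.corrected, result.maps.lv_mask,
                                      self._phantom_tissue(result, truth),
                                      result.timing)
        flows = table["median_mbf"].to_numpy()
        assert np.ptp(flows) / flows.mean() < 0.02

    def test_partial_volume_rim_inflates_low_threshold_mbf(self):
        spec = PhantomSpec(seed=22, pv_rim_width=1.5, pv_rim_frac=0.5)
        series, truth = generate_phantom(spec)
        result = run_pipeline(series)
        table = threshold_sensitivity(result.corrected, result.maps.lv_mask,
                                      self._phantom_tissue(result, truth),
                                      result.timing)
        by_q = dict(zip(table["percentile"], table["median_mbf"]))
        assert by_q[25] >= by_q[75]

    def test_empty_percentile_list_gives_empty_table(self, default_phantom):
        series, truth = default_phantom
        result = run_pipeline(series)
        table = threshold_sensitivity(result.corrected, result.maps.lv_mask,
                                      self._phantom_tissue(result, truth),
                                      result.timing, qs=())
        assert len(table) == 0
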