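import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from aifx.aif import (AIFCurve, ExtractionError, TimingError, TimingPoints,
                      compare_aifs, curve_metrics, extract_aif,
                      resample_half_second, timing_points)
from aifx.bolus import gamma_variate
from aifx.io import PerfusionSeries


class TestResample:
    def test_linear_interpolation_onto_half_second_grid(self):
        c = resample_half_second([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        np.testing.assert_allclose(c.times, [0, 0.5, 1, 1.5, 2])
        np.testing.assert_allclose(c.values, [0, 1, 2, 3, 4])

    def test_input_on_grid_is_identity(self):
        t = np.arange(0, 5, 0.5)
        v = np.sin(t)
        c = resample_half_second(t, v)
        np.testing.assert_allclose(c.times, t)
        np.testing.assert_allclose(c.values, v)

    @given(st.lists(st.floats(0, 100), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_input_stays_monotone(self, increments):
        v = np.cumsum(np.abs(increments))
        t = np.arange(len(v), dtype=float)
        c = resample_half_second(t, v)
        assert np.all(np.diff(c.values) >= -1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            resample_half_second([1.0], [2.0])


class TestExtractAif:
    def _series_with_mip(self, mip_values):
        """Series whose per-pixel temporal max equals the given values."""
        n = len(mip_values)
        data = np.zeros((12, 1, n))
        for j, m in enumerate(mip_values):
            data[:, 0, j] = m * np.linspace(0, 1, 12)
        return PerfusionSeries(data, np.arange(12.0))

    def test_range_threshold(self):
        s = self._series_with_mip([10, 20, 30, 40, 50])
        mask = np.ones((1, 5), bool)
        c = extract_aif(s, mask, percentile=75)
        assert c.threshold == pytest.approx(40.0)
        assert c.pixel_mask.sum() == 2  # MIP 40 and 50 survive

    def test_selected_counts_nest_with_percentile(self):
        rng = np.random.default_rng(0)
        s = self._series_with_mip(rng.uniform(10, 50, size=30))
        mask = np.ones((1, 30), bool)
        counts = [extract_aif(s, mask, percentile=q).pixel_mask.sum()
                  for q in (25, 50, 75)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_peak_value_non_increasing_with_lower_percentile(self):
        rng = np.random.default_rng(1)
        s = self._series_with_mip(rng.uniform(10, 50, size=30))
        mask = np.ones((1, 30), bool)
        peaks = [extract_aif(s, mask, percentile=q).values.max()
                 for q in (75, 50, 25)]
        assert peaks[0] >= peaks[1] >= peaks[2]

    def test_empty_mask_rejected(self):
        s = self._series_with_mip([10, 20])
        with pytest.raises(ExtractionError):
            extract_aif(s, np.zeros((1, 2), bool))

    def test_selected_pixels_subset_of_mask(self, pipeline_result):
        res = pipeline_result
        assert not np.any(res.aif.pixel_mask & ~res.maps.lv_mask)

    def test_papillary_pixels_excluded_at_default_threshold(
            self, default_phantom, pipeline_result):
        _, truth = default_phantom
        res = pipeline_result
        pap = truth.mask_in_frame(truth.papillary_mask, res.reference_index)
        assert (res.aif.pixel_mask & pap).sum() == 0


def _piecewise_curve():
    # flat 0 on [0, 5] s, then linear to 100 at t = 10 s, linear back down
    t = np.arange(0, 15.5, 0.5)
    v = np.where(t <= 5, 0.0, np.where(t <= 10, (t - 5) * 20.0,
                                       np.maximum(100 - (t - 10) * 20.0, 0.0)))
    return AIFCurve(times=t, values=v)


class TestTimingPoints:
    def test_piecewise_linear_geometry(self):
        tp = timing_points(_piecewise_curve())
        assert tp.peak_time == pytest.approx(10.0)
        assert tp.start_time == pytest.approx(5.0)
        assert 0.0 <= tp.baseline_time <= 5.0

    def test_gamma_variate_peak_on_grid(self):
        t = np.arange(0, 30, 0.5)
        v = gamma_variate(t, 6.0, 100.0, 3.0, 2.0)
        tp = timing_points(AIFCurve(times=t, values=v))
        assert tp.peak_time == pytest.approx(12.0)  # t0 + alpha*beta

    def test_translation_equivariance(self):
        t = np.arange(0, 30, 0.5)
        v = gamma_variate(t, 6.0, 100.0, 3.0, 2.0)
        tp = timing_points(AIFCurve(times=t, values=v))
        shifted = timing_points(AIFCurve(times=t + 7.5, values=v))
        assert shifted.peak_time == pytest.approx(tp.peak_time + 7.5)
        assert shifted.start_time == pytest.approx(tp.start_time + 7.5)
        assert shifted.baseline_time == pytest.approx(tp.baseline_time + 7.5)

    def test_flat_curve_rejected(self):
        c = AIFCurve(times=np.arange(0, 5, 0.5), values=np.full(10, 3.0))
        with pytest.raises(TimingError):
            timing_points(c)

    def test_boundary_peak_rejected(self):
        c = AIFCurve(times=np.arange(0, 5, 0.5), values=np.arange(10.0))
        with pytest.raises(TimingError):
            timing_points(c)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(TimingError):
            TimingPoints(baseline_time=5.0, start_time=4.0, peak_time=10.0)


class TestCurveMetrics:
    def test_m_value_arithmetic(self):
        # PV 2.0, TTP 4.0, FWHM 8.0 -> M = 2 / 32 = 0.0625
        t = np.arange(0, 20.5, 0.5)
        peak_t, width = 10.0, 8.0
        v = np.clip(2.0 * (1 - np.abs(t - peak_t) / width), 0, None)
        c = AIFCurve(times=t, values=v)
        tp = TimingPoints(baseline_time=0.0, start_time=6.0, peak_time=10.0)
        m = curve_metrics(c, tp)
        assert m.pv == pytest.approx(2.0)
        assert m.ttp == pytest.approx(4.0)
        assert m.fwhm == pytest.approx(8.0)
        assert m.m_value == pytest.approx(0.0625)

    def test_symmetric_triangle_fwhm(self):
        # height 100, base 10 s -> half height reached 2.5 s either side
        t = np.arange(0, 20.5, 0.5)
        v = np.clip(100.0 * (1 - np.abs(t - 10.0) / 5.0), 0, None)
        c = AIFCurve(times=t, values=v)
        tp = TimingPoints(baseline_time=0.0, start_time=5.0, peak_time=10.0)
        assert curve_metrics(c, tp).fwhm == pytest.approx(5.0)

    def test_gamma_fwhm_matches_root_finding_oracle(self):
        alpha, beta, t0, A = 3.0, 2.0, 6.0, 100.0
        t = np.arange(0, 40, 0.5)
        v = gamma_variate(t, t0, A, alpha, beta)
        c = AIFCurve(times=t, values=v)
        tp = timing_points(c)
        m = curve_metrics(c, tp)
        f = lambda x: gamma_variate(x, t0, A, alpha, beta) - A / 2.0
        peak = t0 + alpha * beta
        left = brentq(f, t0 + 1e-9, peak)
        right = brentq(f, peak, 60.0)
        assert m.fwhm == pytest.approx(right - left, abs=0.5)

    def test_fwhm_clipped_when_no_downcrossing(self):
        t = np.arange(0, 10.5, 0.5)
        v = np.minimum(t * 10.0, 60.0)
        v[-1] = 59.0  # interior peak, but never falls below half height
        c = AIFCurve(times=t, values=v)
        tp = TimingPoints(baseline_time=0.0, start_time=0.5, peak_time=6.0)
        assert curve_metrics(c, tp).fwhm_clipped


class TestCompareAifs:
    def _gamma_curve(self, scale=1.0, offset=0.0):
        t = np.arange(0, 30, 0.5)
        return AIFCurve(times=t,
                        values=scale * gamma_variate(t, 6, 100, 2.5, 1.8) + offset)

    def test_identical_curves(self):
        a = self._gamma_curve()
        r, nrmse = compare_aifs(a, a)
        assert r == pytest.approx(1.0)
        assert nrmse == pytest.approx(0.0)

    def test_affine_transform_keeps_r_but_not_nrmse(self):
        a = self._gamma_curve()
        b = self._gamma_curve(scale=2.0, offset=5.0)
        r, nrmse = compare_aifs(a, b)
        assert r == pytest.approx(1.0)
        assert nrmse > 0.0

    def test_noise_nrmse_matches_propagation(self):
        a = self._gamma_curve()
        rng = np.random.default_rng(0)
        sigma = 3.0
        nrmses = []
        for _ in range(200):
            b = AIFCurve(times=a.times,
                         values=a.values + rng.normal(0, sigma, a.values.shape))
            nrmses.append(compare_aifs(a, b)[1])
        expected = sigma / np.ptp(a.values) * 100.0
        assert np.mean(nrmses) == pytest.approx(expected, rel=0.1)

    def test_too_little_overlap_rejected(self):
        a = self._gamma_curve()
        b = AIFCurve(times=np.array([29.0, 29.5]), values=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            compare_aifs(a, b)
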