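import itertools

import numpy as np
import pytest

from aifx.bolus import gamma_variate
from aifx.heartdetect import (EmptyCandidateError, InsufficientCandidatesError,
                              RegionCandidate, filter_candidates, heart_box,
                              merge_similar, std_map, threshold_candidates,
                              vote_scores, vote_ventricles)
from aifx.io import PerfusionSeries
from aifx.motion import reference_frame_index


def _series_from_curves(curve_by_mask, shape=(16, 20), T=60, noise=0.0, seed=0):
    """Build a series assigning a temporal curve to each boolean mask."""
    rng = np.random.default_rng(seed)
    data = np.zeros((T,) + shape)
    for mask, curve in curve_by_mask:
        data[:, mask] = np.asarray(curve)[:, None]
    if noise:
        data += rng.normal(0, noise, size=data.shape)
    return PerfusionSeries(data, np.arange(T, dtype=float))


def _disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestStdMap:
    def test_constant_pixel_is_zero(self):
        s = PerfusionSeries(np.full((12, 4, 4), 3.0), np.arange(12.0))
        assert np.all(std_map(s) == 0)

    def test_alternating_pixel_population_sd(self):
        data = np.zeros((12, 2, 2))
        data[::2, 0, 0] = 0.0
        data[1::2, 0, 0] = 2.0
        s = PerfusionSeries(data, np.arange(12.0))
        assert std_map(s)[0, 0] == pytest.approx(1.0)

    def test_lv_exceeds_background_on_clean_phantom(self, clean_phantom):
        series, truth = clean_phantom
        sd = std_map(series)
        assert sd[truth.lv_mask].min() > sd[~truth.heart_mask()].max()


class TestThresholdCandidates:
    def test_threshold_uses_map_statistics_and_kind(self):
        t = np.arange(60.0)
        curve = gamma_variate(t, 10, 100, 2.5, 1.8)
        mask = _disc_mask((16, 20), (8, 10), 4)
        series = _series_from_curves([(mask, curve)], noise=1.0)
        sd = std_map(series)
        cands = threshold_candidates(sd, series, k_sigma=1.0, min_px=4)
        expected = sd > sd.mean() + sd.std()
        union = np.zeros_like(mask)
        for c in cands:
            union |= c.mask
        # candidate pixels are exactly the above-threshold pixels (all in
        # one sufficiently large component here)
        np.testing.assert_array_equal(union, expected)

    def test_no_pixels_above_threshold_raises(self):
        s = PerfusionSeries(np.full((12, 6, 6), 5.0), np.arange(12.0))
        with pytest.raises(EmptyCandidateError):
            threshold_candidates(np.zeros((6, 6)), s)

    def test_phantom_chambers_each_overlap_a_candidate(self, clean_phantom):
        series, truth = clean_phantom
        cands = threshold_candidates(std_map(series), series)
        def best_dice(mask):
            return max(2 * (c.mask & mask).sum() / (c.mask.sum() + mask.sum())
                       for c in cands)
        assert best_dice(truth.lv_mask) > 0.5
        assert best_dice(truth.rv_mask) > 0.5


def _cand(curve, mask=None, T=60):
    if mask is None:
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
    return RegionCandidate(mask=mask, times=np.arange(float(len(curve))),
                           curve=np.asarray(curve, dtype=float))


class TestFilterCandidates:
    def test_weak_enhancement_removed(self):
        # baseline 50, peak 90: 1.8x < 2x enhancement
        curve = np.full(60, 50.0)
        curve[25:30] = 90.0
        good = gamma_variate(np.arange(60.0), 15, 100, 2.5, 1.8) + 10
        kept = filter_candidates([_cand(curve), _cand(good)])
        assert len(kept) == 1
        assert kept[0].curve.max() > 100

    def test_boundary_peak_removed(self):
        early = np.ones(60)
        early[1] = 100.0
        late = np.ones(60)
        late[58] = 100.0
        good = gamma_variate(np.arange(60.0), 15, 100, 2.5, 1.8) + 10
        kept = filter_candidates([_cand(early), _cand(late), _cand(good)])
        assert len(kept) == 1

    def test_ventricle_like_candidate_retained(self):
        curve = gamma_variate(np.arange(60.0), 18, 90, 2.5, 1.8) + 10
        assert len(filter_candidates([_cand(curve)])) == 1

    def test_all_removed_raises(self):
        with pytest.raises(EmptyCandidateError):
            filter_candidates([_cand(np.full(60, 50.0))])


class TestMergeSimilar:
    def test_split_region_with_identical_dynamics_merges(self):
        t = np.arange(60.0)
        curve = gamma_variate(t, 12, 100, 2.5, 1.8)
        disc = _disc_mask((16, 20), (8, 10), 5)
        left = disc & (np.arange(20)[None, :] < 9)
        right = disc & (np.arange(20)[None, :] > 10)  # 2-px dark stripe
        series = _series_from_curves([(left, curve), (right, curve)], noise=0.5)
        cands = [RegionCandidate(mask=m, times=t,
                                 curve=series.data[:, m].mean(axis=1))
                 for m in (left, right)]
        merged = merge_similar(cands, series)
        assert len(merged) == 1
        assert merged[0].area == left.sum() + right.sum()

    def test_distant_regions_not_merged(self):
        t = np.arange(60.0)
        curve = gamma_variate(t, 12, 100, 2.5, 1.8)
        a = _disc_mask((16, 40), (8, 5), 2)
        b = _disc_mask((16, 40), (8, 35), 2)
        series = _series_from_curves([(a, curve), (b, curve)], shape=(16, 40))
        cands = [RegionCandidate(mask=m, times=t,
                                 curve=series.data[:, m].mean(axis=1))
                 for m in (a, b)]
        assert len(merge_similar(cands, series)) == 2

    def test_touching_but_uncorrelated_not_merged(self):
        t = np.arange(60.0)
        a_mask = np.zeros((10, 10), bool)
        a_mask[4:6, 2:4] = True
        b_mask = np.zeros((10, 10), bool)
        b_mask[4:6, 4:6] = True
        a_curve = gamma_variate(t, 10, 100, 2.5, 1.8)
        b_curve = 100 - a_curve  # strongly anti-correlated
        series = _series_from_curves([(a_mask, a_curve), (b_mask, b_curve)],
                                     shape=(10, 10))
        cands = [RegionCandidate(mask=a_mask, times=t, curve=a_curve),
                 RegionCandidate(mask=b_mask, times=t, curve=b_curve)]
        assert len(merge_similar(cands, series)) == 2


def _rank_oracle(table, names, larger_better):
    """Exhaustive rank enumeration: sort each feature, assign 1..N scores."""
    n = len(table)
    totals = np.zeros(n)
    for name in names:
        vals = [row[name] if larger_better[name] else -row[name] for row in table]
        for i in range(n):
            # average-rank convention: 1 + #worse + (#tied - 1)/2
            worse = sum(1 for v in vals if v < vals[i])
            tied = sum(1 for v in vals if v == vals[i])
            totals[i] += 1 + worse + (tied - 1) / 2.0
    return totals


class TestVoting:
    NAMES = ["area", "pv", "upslope", "m_value", "ttp", "fwhm", "dist_center"]
    LARGER = {"area": True, "pv": True, "upslope": True, "m_value": True,
              "ttp": False, "fwhm": False, "dist_center": False}

    def _table(self, rows):
        keys = self.NAMES
        return [dict(zip(keys, r)) for r in rows]

    def test_scores_match_exhaustive_enumeration(self):
        table = self._table([
            [30, 100, 25, 3.0, 4.0, 6.0, 5.0],
            [45, 80, 20, 2.0, 3.5, 7.0, 9.0],
            [10, 60, 30, 2.5, 5.0, 5.0, 2.0],
        ])
        got = vote_scores(table, self.NAMES)
        want = _rank_oracle(table, self.NAMES, self.LARGER)
        np.testing.assert_allclose(got, want)

    def test_scores_match_enumeration_with_ties(self):
        table = self._table([
            [30, 100, 25, 3.0, 4.0, 6.0, 5.0],
            [30, 100, 20, 2.0, 4.0, 7.0, 9.0],
            [10, 60, 25, 2.5, 5.0, 5.0, 5.0],
        ])
        got = vote_scores(table, self.NAMES)
        want = _rank_oracle(table, self.NAMES, self.LARGER)
        np.testing.assert_allclose(got, want)

    def test_per_feature_scores_sum_to_rank_identity(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 8):
            table = self._table(rng.uniform(1, 100, size=(n, len(self.NAMES))))
            for name in self.NAMES:
                s = vote_scores(table, [name])
                assert s.sum() == pytest.approx(n * (n + 1) / 2)

    def test_dominant_candidate_selected_first(self, clean_phantom):
        t = np.arange(60.0)
        big = gamma_variate(t, 10, 120, 2.0, 1.5) + 5   # high PV, early, sharp
        small = gamma_variate(t, 20, 40, 4.0, 3.0) + 5
        m_big = _disc_mask((20, 20), (10, 10), 5)       # large and central
        m_small = _disc_mask((20, 20), (3, 3), 2)
        cands = [RegionCandidate(mask=m_small, times=t, curve=small),
                 RegionCandidate(mask=m_big, times=t, curve=big)]
        first, second = vote_ventricles(cands, (20, 20))
        assert first is cands[1]

    def test_selection_invariant_to_candidate_order(self):
        t = np.arange(60.0)
        curves = [gamma_variate(t, 8 + 3 * k, 60 + 20 * k, 2.5, 1.8) + 5
                  for k in range(3)]
        masks = [_disc_mask((24, 24), (6 + 6 * k, 12), 2 + k) for k in range(3)]
        cands = [RegionCandidate(mask=m, times=t, curve=c)
                 for m, c in zip(masks, curves)]
        baseline = vote_ventricles(cands, (24, 24))
        base_ids = {id(baseline[0]), id(baseline[1])}
        for perm in itertools.permutations(cands):
            sel = vote_ventricles(list(perm), (24, 24))
            assert {id(sel[0]), id(sel[1])} == base_ids

    def test_fewer_than_two_candidates_raises(self):
        c = _cand(gamma_variate(np.arange(60.0), 15, 100, 2.5, 1.8))
        with pytest.raises(InsufficientCandidatesError):
            vote_ventricles([c], (8, 8))


class TestHeartBox:
    def test_zero_margin_box_is_tight_union(self):
        a = np.zeros((40, 40), bool)
        a[10:18, 8:20] = True
        b = np.zeros((40, 40), bool)
        b[12:21, 22:31] = True
        t = np.arange(10.0)
        box = heart_box(RegionCandidate(a, t, np.zeros(10)),
                        RegionCandidate(b, t, np.zeros(10)), (40, 40), margin=0.0)
        assert (box.row0, box.col0, box.row1, box.col1) == (10, 8, 21, 31)

    def test_margin_clipped_at_image_border(self):
        a = np.zeros((20, 20), bool)
        a[0:5, 0:5] = True
        b = np.zeros((20, 20), bool)
        b[3:8, 3:8] = True
        t = np.arange(10.0)
        box = heart_box(RegionCandidate(a, t, np.zeros(10)),
                        RegionCandidate(b, t, np.zeros(10)), (20, 20), margin=0.5)
        assert box.row0 == 0 and box.col0 == 0
        assert box.row1 <= 20 and box.col1 <= 20

    def test_phantom_box_contains_ventricles(self, default_phantom, pipeline_result):
        _, truth = default_phantom
        res = pipeline_result
        chambers = truth.mask_in_frame(truth.lv_mask | truth.rv_mask,
                                       res.reference_index)
        inside = chambers & res.box.mask(chambers.shape)
        assert inside.sum() >= 0.99 * chambers.sum()
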