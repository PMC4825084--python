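"""Heart region detection from the temporal standard-deviation map.

Pixels traversed by the contrast bolus vary strongly over time, so a
pixel-wise temporal standard-deviation map highlights the ventricles while
suppressing constantly bright structures such as the chest wall.  The map
is thresholded at mean + k*SD (k = 1 for the low-resolution AIF series,
k = 2 for the myocardial series); connected components become candidate
ventricle regions.  Candidates that do not behave like ventricles are
dropped (peak below twice the baseline intensity, or peak within the first
or last three frames), split regions with near-identical dynamics are
merged, and a linear rank-voting scheme over time-signal and geometric
features selects the two regions most characteristic of the RV and LV.
Their union, expanded by a margin, becomes the heart bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from skimage.measure import label, regionprops

from .aif import TimingError, curve_metrics, resample_half_second, timing_points
from .io import PerfusionSeries

DEFAULT_MIN_PX = {"aif": 4, "myocardial": 16}
K_SIGMA = {"aif": 1.0, "myocardial": 2.0}

__all__ = [
    "RegionCandidate",
    "HeartBox",
    "EmptyCandidateError",
    "InsufficientCandidatesError",
    "std_map",
    "threshold_candidates",
    "filter_candidates",
    "merge_similar",
    "vote_ventricles",
    "heart_box",
    "candidate_features",
]


class EmptyCandidateError(RuntimeError):
    """No candidate ventricle regions survive thresholding/filtering."""


class InsufficientCandidatesError(RuntimeError):
    """Fewer than two candidates available for ventricle voting."""


@dataclass
class RegionCandidate:
    """A connected candidate ventricle region with its mean time-signal curve."""

    mask: np.ndarray
    times: np.ndarray
    curve: np.ndarray
    features: dict = field(default_factory=dict)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def avg_radius(self) -> float:
        return float(np.sqrt(self.area / np.pi))

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class HeartBox:
    """Half-open bounding rectangle (row0, col0, row1, col1) around the heart."""

    row0: int
    col0: int
    row1: int
    col1: int
    first: Optional[RegionCandidate] = None
    second: Optional[RegionCandidate] = None

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row0 : self.row1, self.col0 : self.col1] = True
        return m


def std_map(series: PerfusionSeries) -> np.ndarray:
    """Pixel-wise temporal standard deviation (population, 1/T) map."""
    return series.data.std(axis=0)


def _candidate_from_mask(mask: np.ndarray, series: PerfusionSeries) -> RegionCandidate:
    curve = series.data[:, mask].mean(axis=1)
    return RegionCandidate(mask=mask, times=series.frame_times.copy(), curve=curve)


def threshold_candidates(sd: np.ndarray, series: PerfusionSeries,
                         k_sigma: Optional[float] = None,
                         min_px: Optional[int] = None) -> list[RegionCandidate]:
    """Binarise the SD map at mean + k*SD and extract connected candidates.

    k defaults to 1 for the AIF series and 2 for the myocardial series; the
    map statistics are taken over the whole image.  8-connected components
    of at least ``min_px`` pixels become candidates, with mean curves drawn
    from the (motion-corrected) series.
    """
    if k_sigma is None:
        k_sigma = K_SIGMA[series.kind]
    if min_px is None:
        min_px = DEFAULT_MIN_PX[series.kind]
    if not np.all(np.isfinite(sd)):
        raise ValueError("SD map contains non-finite values")
    thr = sd.mean() + k_sigma * sd.std()
    binary = sd > thr
    if not binary.any():
        raise EmptyCandidateError("no pixels above the SD-map threshold")
    lab = label(binary, connectivity=2)
    cands = []
    for p in regionprops(lab):
        if p.area < min_px:
            continue
        cands.append(_candidate_from_mask(lab == p.label, series))
    if not cands:
        raise EmptyCandidateError("no connected region reaches the minimum size")
    return cands


def filter_candidates(cands: Sequence[RegionCandidate], n_edge_frames: int = 3,
                      baseline_frames: int = 3,
                      min_enhancement_ratio: float = 2.0) -> list[RegionCandidate]:
    """Drop candidates without ventricle-like enhancement dynamics.

    A candidate is removed when its peak intensity is below
    ``min_enhancement_ratio`` times its baseline intensity (mean of the first
    ``baseline_frames`` frames), or when its peak falls within the first or
    last ``n_edge_frames`` frames of the series.
    """
    kept = []
    for c in cands:
        T = len(c.curve)
        baseline = float(c.curve[:baseline_frames].mean())
        peak_idx = int(np.argmax(c.curve))
        if baseline > 0 and c.curve[peak_idx] < min_enhancement_ratio * baseline:
            continue
        if peak_idx < n_edge_frames or peak_idx >= T - n_edge_frames:
            continue
        kept.append(c)
    if not kept:
        raise EmptyCandidateError("all candidates removed by dynamics filters")
    return kept


def _min_distance(a: RegionCandidate, b: RegionCandidate) -> float:
    pa = np.argwhere(a.mask)
    pb = np.argwhere(b.mask)
    return float(cdist(pa, pb).min())


def merge_similar(cands: Sequence[RegionCandidate], series: PerfusionSeries,
                  corr_threshold: float = 0.75) -> list[RegionCandidate]:
    """Union candidates that are one ventricle split by dark structures.

    Two candidates merge when their mean curves' Pearson correlation exceeds
    ``corr_threshold`` and their minimum inter-pixel Euclidean distance is
    below the sum of their average radii; merging is transitive and merged
    curves are recomputed over the union of pixels.
    """
    n = len(cands)
    if n <= 1:
        return list(cands)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = cands[i], cands[j]
            if np.std(ci.curve) == 0 or np.std(cj.curve) == 0:
                continue
            r = float(np.corrcoef(ci.curve, cj.curve)[0, 1])
            if r <= corr_threshold:
                continue
            if _min_distance(ci, cj) >= ci.avg_radius + cj.avg_radius:
                continue
            parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(cands[members[0]])
        else:
            mask = np.zeros_like(cands[members[0]].mask)
            for m in members:
                mask |= cands[m].mask
            merged.append(_candidate_from_mask(mask, series))
    return merged


def candidate_features(c: RegionCandidate, image_shape: tuple[int, int]) -> dict:
    """Time-signal and geometric features of a candidate, robust to odd curves.

    PV, TTP, FWHM, upslope and M-value are measured on the 0.5 s-resampled
    mean curve via the timing-point detector; when that detector cannot run
    (e.g. boundary peak), crude fallbacks keep every feature finite so the
    candidate still participates in voting.
    """
    resampled = resample_half_second(c.times, c.curve)
    t, v = resampled.times, resampled.values
    peak_idx = int(np.argmax(v))
    baseline = float(v[: max(2, int(3 / (t[1] - t[0])))].min())
    try:
        tp = timing_points(resampled)
        m = curve_metrics(resampled, tp)
        pv, ttp, fwhm, upslope, mval = m.pv, m.ttp, m.fwhm, m.upslope, m.m_value
    except (TimingError, ValueError):
        pv = float(v[peak_idx] - baseline)
        ttp = float(max(t[peak_idx] - t[0], t[1] - t[0]))
        fwhm = float(t[-1] - t[0])
        upslope = pv / ttp if ttp > 0 else 0.0
        mval = pv / (ttp * fwhm) if ttp > 0 and fwhm > 0 else 0.0
    cy, cx = c.centroid
    dist_center = float(np.hypot(cy - image_shape[0] / 2.0, cx - image_shape[1] / 2.0))
    feats = {
        "area": float(c.area), "pv": float(max(pv, 1e-12)), "ttp": float(ttp),
        "fwhm": float(fwhm), "upslope": float(upslope), "m_value": float(mval),
        "dist_center": dist_center,
    }
    c.features = feats
    return feats


# feature name -> whether larger values are more ventricle-like
FEATURE_LARGER_BETTER = {
    "area": True, "pv": True, "upslope": True, "m_value": True,
    "ttp": False, "fwhm": False, "dist_center": False, "dist_selected": False,
}


def vote_scores(table: Sequence[dict], feature_names: Sequence[str]) -> np.ndarray:
    """Total linear-voting score per candidate.

    For each feature the candidates are ranked (ties share the average
    rank) and converted to scores 1..N, N going to the most ventricle-like
    value; scores are summed over features.
    """
    n = len(table)
    totals = np.zeros(n)
    for name in feature_names:
        vals = np.array([row[name] for row in table], dtype=float)
        goodness = vals if FEATURE_LARGER_BETTER[name] else -vals
        totals += rankdata(goodness, method="average")
    return totals


def _select_one(cands, tables, feature_names, exclude: set) -> int:
    idx = [i for i in range(len(cands)) if i not in exclude]
    sub = [tables[i] for i in idx]
    totals = vote_scores(sub, feature_names)
    best = np.flatnonzero(totals == totals.max())
    if len(best) > 1:  # tie-break: larger M-value, then closer to image centre
        mvals = np.array([sub[i]["m_value"] for i in best])
        best = best[mvals == mvals.max()]
        if len(best) > 1:
            dists = np.array([sub[i]["dist_center"] for i in best])
            best = best[dists == dists.min()]
    return idx[int(best[0])]


def vote_ventricles(cands: Sequence[RegionCandidate],
                    image_shape: tuple[int, int]) -> tuple[RegionCandidate, RegionCandidate]:
    """Select the two candidates most characteristic of the RV and LV.

    Two voting rounds: the first uses region size, PV, upslope, M-value,
    TTP, FWHM and distance to the image centre; the second additionally
    scores the minimum distance to the already-selected region, so the
    second pick is both ventricle-like and near the first.
    """
    if len(cands) < 2:
        raise InsufficientCandidatesError(
            f"need at least 2 candidates to vote, have {len(cands)}"
        )
    tables = [candidate_features(c, image_shape) for c in cands]
    base_features = ["area", "pv", "upslope", "m_value", "ttp", "fwhm", "dist_center"]
    first_idx = _select_one(cands, tables, base_features, exclude=set())
    for i, c in enumerate(cands):
        tables[i]["dist_selected"] = (
            0.0 if i == first_idx else _min_distance(c, cands[first_idx])
        )
    second_idx = _select_one(cands, tables, base_features + ["dist_selected"],
                             exclude={first_idx})
    return cands[first_idx], cands[second_idx]


def heart_box(first: RegionCandidate, second: RegionCandidate,
              image_shape: tuple[int, int], margin: float = 0.25) -> HeartBox:
    """Tight union box of the two selected regions, expanded by ``margin``.

    The margin is a fraction of the box height/width added to each side;
    the result is clipped to the image.
    """
    union = first.mask | second.mask
    rr, cc = np.nonzero(union)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    mr = int(round((r1 - r0) * margin))
    mc = int(round((c1 - c0) * margin))
    return HeartBox(
        row0=max(0, r0 - mr), col0=max(0, c0 - mc),
        row1=min(image_shape[0], r1 + mr), col1=min(image_shape[1], c1 + mc),
        first=first, second=second,
    )
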