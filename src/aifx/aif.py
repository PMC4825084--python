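"""AIF extraction, timing-point detection and curve quality metrics.

The arterial input function (AIF) is the time-signal intensity curve of the
contrast bolus in the LV blood pool.  It is extracted by bright-pixel
thresholding of the LV label map: per-pixel temporal maxima (MIP) are
thresholded at a percentile of the LV intensity *range*, the surviving
pixels are averaged per frame, and the curve is linearly resampled onto a
uniform 0.5 s grid.  Dark papillary-muscle pixels and partial-volume rim
pixels fall below the default 75th-percentile threshold and are excluded.

Three timing points are then detected on the curve: baseline (the sample
with minimal intensity variation against its neighbours before the rise),
start of contrast enhancement (the curve point geometrically closest to the
intersection of a line fitted to the rising flank with the baseline level),
and peak.  Quality metrics PV, TTP, FWHM, upslope and the combined
M = PV / (TTP * FWHM) are computed from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

RESAMPLE_DT = 0.5  # seconds

__all__ = [
    "AIFCurve",
    "TimingPoints",
    "AIFMetrics",
    "TimingError",
    "ExtractionError",
    "extract_aif",
    "resample_half_second",
    "timing_points",
    "curve_metrics",
    "compare_aifs",
]


class TimingError(ValueError):
    """Timing points cannot be detected on this curve."""


class ExtractionError(ValueError):
    """AIF pixel selection failed."""


@dataclass
class TimingPoints:
    """Contrast-enhancement timing points of a bolus curve, in seconds."""

    baseline_time: float
    start_time: float
    peak_time: float

    def __post_init__(self) -> None:
        if not (self.baseline_time <= self.start_time < self.peak_time):
            raise TimingError(
                f"timing points out of order: baseline={self.baseline_time}, "
                f"start={self.start_time}, peak={self.peak_time}"
            )

    def shifted(self, dt: float) -> "TimingPoints":
        return TimingPoints(self.baseline_time + dt, self.start_time + dt, self.peak_time + dt)


@dataclass
class AIFMetrics:
    """Bolus-curve quality metrics.

    PV: peak value above baseline (a.u.); TTP: time from contrast start to
    peak (s); FWHM: full width at half maximum above baseline (s); upslope:
    maximal rising slope (a.u./s); m_value = PV / (TTP * FWHM) (a.u./s^2).
    ``fwhm_clipped`` flags a right half-height crossing that never occurs
    before the series ends.
    """

    pv: float
    ttp: float
    fwhm: float
    upslope: float
    m_value: float
    fwhm_clipped: bool = False


@dataclass
class AIFCurve:
    """A time-signal intensity curve on a uniform 0.5 s grid."""

    times: np.ndarray
    values: np.ndarray
    pixel_mask: Optional[np.ndarray] = None
    percentile: Optional[float] = None
    threshold: Optional[float] = None
    timing: Optional[TimingPoints] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AIF values must be finite")

    def __len__(self) -> int:
        return len(self.times)


def resample_half_second(times: Sequence[float], values: Sequence[float]) -> AIFCurve:
    """Linearly resample a curve onto the grid t = t0, t0+0.5, ... (seconds).

    No extrapolation: the grid ends at the last input time.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 samples to resample")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    t0 = times[0]
    n = int(np.floor((times[-1] - t0) / RESAMPLE_DT + 1e-9)) + 1
    grid = t0 + RESAMPLE_DT * np.arange(n)
    return AIFCurve(times=grid, values=np.interp(grid, times, values))


def extract_aif(series, lv_mask: np.ndarray, percentile: float = 75.0,
                mode: str = "range") -> AIFCurve:
    """Extract the AIF from the bright pixels of the LV region.

    The per-pixel temporal maximum intensity projection (MIP) is computed
    over ``lv_mask``; the threshold is ``MIPmin + (q/100) * (MIPmax -
    MIPmin)`` (``mode="range"``, the default) or the q-th order statistic of
    the MIP values (``mode="quantile"``).  Pixels at or above the threshold
    are averaged per frame and the result resampled at 0.5 s.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not lv_mask.any():
        raise ExtractionError("empty LV mask")
    mip = series.data.max(axis=0)
    vals = mip[lv_mask]
    if mode == "range":
        thr = vals.min() + (percentile / 100.0) * (vals.max() - vals.min())
    elif mode == "quantile":
        thr = float(np.percentile(vals, percentile))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    selected = lv_mask & (mip >= thr)
    if not selected.any():
        raise ExtractionError("no LV pixels above threshold")
    raw = series.data[:, selected].mean(axis=1)
    curve = resample_half_second(series.frame_times, raw)
    curve.pixel_mask = selected
    curve.percentile = float(percentile)
    curve.threshold = float(thr)
    return curve


def _rising_segment(values: np.ndarray, peak_idx: int) -> tuple[int, int]:
    """Index range [i0, i1] of samples on the steep rising flank before the peak.

    The flank is the contiguous run of forward differences, containing the
    maximal one, that stay above half the maximal forward difference.
    """
    fwd = np.diff(values[: peak_idx + 1])
    anchor = int(np.argmax(fwd))
    lim = 0.5 * fwd[anchor]
    i0 = anchor
    while i0 > 0 and fwd[i0 - 1] >= lim:
        i0 -= 1
    i1 = anchor
    while i1 < len(fwd) - 1 and fwd[i1 + 1] >= lim:
        i1 += 1
    return i0, i1 + 1  # inclusive sample range covering the run's endpoints


def timing_points(curve: AIFCurve) -> TimingPoints:
    """Detect baseline, contrast-start and peak times on a bolus curve.

    Peak: argmax of the curve.  Baseline: the sample minimising the summed
    absolute difference to its two neighbours, searched before the point of
    maximal intensity increase.  Start: a least-squares line is fitted to the
    rising flank; the curve sample geometrically closest (in normalised
    time/intensity coordinates) to the intersection of that line with the
    horizontal baseline level is taken as the start of contrast enhancement.
    """
    t = curve.times
    v = curve.values
    if len(v) < 5:
        raise TimingError("curve too short for timing detection")
    if np.ptp(v) == 0:
        raise TimingError("flat curve: no contrast enhancement")
    peak_idx = int(np.argmax(v))
    if peak_idx in (0, len(v) - 1):
        raise TimingError("peak at series boundary")

    fwd = np.diff(v[: peak_idx + 1])
    anchor = int(np.argmax(fwd))  # point of maximal intensity change before peak

    # baseline: minimal variation w.r.t. both neighbours, before the rise
    if anchor <= 1:
        base_idx = 0
    else:
        i = np.arange(1, anchor)
        var = np.abs(v[i - 1] - v[i]) + np.abs(v[i + 1] - v[i])
        base_idx = int(i[np.argmin(var)])
    baseline_level = v[base_idx]

    i0, i1 = _rising_segment(v, peak_idx)
    seg = slice(i0, i1 + 1)
    if i1 - i0 < 1:
        raise TimingError("degenerate rising segment")
    slope, intercept = np.polyfit(t[seg], v[seg], 1)
    if slope <= 0:
        raise TimingError("non-positive rising slope")
    t_star = (baseline_level - intercept) / slope

    # nearest curve sample to the intersection point, scale-free coordinates
    span_t = t[-1] - t[0]
    span_v = v[peak_idx] - baseline_level
    cand = np.arange(base_idx, peak_idx)
    d2 = ((t[cand] - t_star) / span_t) ** 2 + ((v[cand] - baseline_level) / span_v) ** 2
    start_idx = int(cand[np.argmin(d2)])

    return TimingPoints(
        baseline_time=float(t[base_idx]),
        start_time=float(t[start_idx]),
        peak_time=float(t[peak_idx]),
    )


def _half_crossings(t: np.ndarray, v: np.ndarray, peak_idx: int,
                    half: float) -> tuple[float, float, bool]:
    left = t[peak_idx]
    for i in range(peak_idx, 0, -1):
        if v[i - 1] < half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    else:
        left = t[0]
    clipped = False
    right = t[-1]
    for i in range(peak_idx, len(v) - 1):
        if v[i] >= half > v[i + 1]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    else:
        clipped = True
    return left, right, clipped


def curve_metrics(curve: AIFCurve, tp: TimingPoints,
                  upslope_window: int = 3) -> AIFMetrics:
    """Compute PV, TTP, FWHM, upslope and the M-value of a bolus curve.

    PV is the peak above the baseline level; TTP is peak time minus start
    time; FWHM is measured at baseline + PV/2 with linear interpolation
    between samples (right edge clipped at the series end, with a flag, if
    the curve never falls back below half height); upslope is the maximal
    least-squares slope over a sliding window between start and peak;
    M = PV / (TTP * FWHM).
    """
    t = curve.times
    v = curve.values
    peak_idx = int(np.argmax(v))
    baseline_level = float(np.interp(tp.baseline_time, t, v))
    pv = float(v[peak_idx] - baseline_level)
    if pv <= 0:
        raise TimingError("non-positive peak value")
    ttp = tp.peak_time - tp.start_time
    half = baseline_level + pv / 2.0
    left, right, clipped = _half_crossings(t, v, peak_idx, half)
    fwhm = float(right - left)

    start_idx = int(np.searchsorted(t, tp.start_time))
    w = max(2, upslope_window)
    upslope = 0.0
    if peak_idx - start_idx + 1 >= w:
        for i in range(start_idx, peak_idx - w + 2):
            s = np.polyfit(t[i : i + w], v[i : i + w], 1)[0]
            upslope = max(upslope, float(s))
    else:
        dt = tp.peak_time - tp.start_time
        upslope = float((v[peak_idx] - v[start_idx]) / dt) if dt > 0 else 0.0

    m = pv / (ttp * fwhm) if ttp > 0 and fwhm > 0 else float("nan")
    return AIFMetrics(pv=pv, ttp=float(ttp), fwhm=fwhm, upslope=upslope,
                      m_value=float(m), fwhm_clipped=clipped)


def compare_aifs(a: AIFCurve, b: AIFCurve) -> tuple[float, float]:
    """Similarity of two AIF curves: (Pearson r, NRMSE in percent).

    Curves are intersected on their overlapping time range and curve ``b``
    is interpolated onto ``a``'s grid there.  NRMSE is the RMS difference
    normalised by the intensity range of the reference curve ``a``.
    """
    t0 = max(a.times[0], b.times[0])
    t1 = min(a.times[-1], b.times[-1])
    sel = (a.times >= t0 - 1e-9) & (a.times <= t1 + 1e-9)
    ta = a.times[sel]
    if len(ta) < 3:
        raise ValueError("fewer than 3 overlapping samples")
    va = a.values[sel]
    vb = np.interp(ta, b.times, b.values)
    r = float(np.corrcoef(va, vb)[0, 1])
    rng = float(va.max() - va.min())
    nrmse = float(np.sqrt(np.mean((va - vb) ** 2)) / rng * 100.0)
    return r, nrmse
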