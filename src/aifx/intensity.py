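"""Surface-coil intensity correction and baseline signal removal.

Phased-array surface coils impose a smooth multiplicative shading on the
images.  The proton-density (PD) frames, acquired without saturation
preparation, are dominated by this coil sensitivity: a 2-D polynomial
surface is least-squares fitted to the averaged PD image — foreground
pixels (above the Otsu threshold) weighted 1, background 0.1 — and every
frame is divided by the surface after normalising it to mean 1 over the
heart region.  Division by a time-constant surface preserves every pixel's
temporal curve shape.  Finally the pre-contrast baseline intensity is
subtracted per pixel.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .aif import TimingError, resample_half_second, timing_points
from .io import PerfusionSeries

__all__ = ["coil_correct", "fit_shading_surface", "remove_baseline", "detect_baseline_frames"]


def _design_matrix(rr: np.ndarray, cc: np.ndarray, shape, order: int) -> np.ndarray:
    y = rr / shape[0]
    x = cc / shape[1]
    cols = [y**i * x**j for i in range(order + 1) for j in range(order + 1 - i)]
    return np.stack(cols, axis=1)


def fit_shading_surface(pd_image: np.ndarray, order: int = 3,
                        background_weight: float = 0.1) -> np.ndarray:
    """Weighted least-squares polynomial surface fit to a PD image.

    Pixels above the Otsu threshold get weight 1, the rest
    ``background_weight``.  A rank-deficient fit falls back to successively
    lower orders with a warning.
    """
    H, W = pd_image.shape
    rr, cc = np.mgrid[:H, :W]
    rr, cc, z = rr.ravel().astype(float), cc.ravel().astype(float), pd_image.ravel()
    try:
        thr = threshold_otsu(pd_image)
        w = np.where(z >= thr, 1.0, background_weight)
    except ValueError:  # constant image
        w = np.ones_like(z)
    sw = np.sqrt(w)
    for o in range(order, -1, -1):
        A = _design_matrix(rr, cc, (H, W), o)
        coef, _, rank, _ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        if rank == A.shape[1]:
            if o < order:
                warnings.warn(f"shading fit rank-deficient at order {order}; using order {o}")
            return (A @ coef).reshape(H, W)
    return np.full((H, W), float(np.average(z, weights=w)))


def coil_correct(series: PerfusionSeries, order: int = 3,
                 heart_box=None, enabled: bool = True) -> PerfusionSeries:
    """Divide every frame by the normalised PD-derived shading surface.

    The surface is scaled to mean 1 over the heart box (whole image when no
    box is given) so correction does not change the overall intensity
    scale.  Without PD frames the operation is a warning no-op.
    """
    if not enabled:
        return series
    if not series.pd_frames:
        warnings.warn("no PD frames available; skipping coil intensity correction")
        return series
    pd_mean = np.mean(series.pd_frames, axis=0)
    surface = fit_shading_surface(pd_mean, order=order)
    if heart_box is not None:
        sl = heart_box.slices()
        norm = surface[sl].mean()
    else:
        norm = surface.mean()
    surface = surface / norm
    surface = np.clip(surface, 1e-3, None)
    out = series.with_data(series.data / surface[np.newaxis])
    out.pd_frames = series.pd_frames
    return out


def detect_baseline_frames(series: PerfusionSeries, fallback_n: int = 3) -> np.ndarray:
    """Indices of pre-contrast frames.

    The start of contrast enhancement is detected on the whole-image mean
    curve; frames strictly before it are the baseline.  When detection
    fails (or leaves no frames), the first ``fallback_n`` frames are used.
    """
    mean_curve = series.data.mean(axis=(1, 2))
    try:
        resampled = resample_half_second(series.frame_times, mean_curve)
        tp = timing_points(resampled)
        idx = np.flatnonzero(series.frame_times < tp.start_time)
        if idx.size:
            return idx
    except (TimingError, ValueError):
        pass
    return np.arange(min(fallback_n, series.n_frames))


def remove_baseline(series: PerfusionSeries,
                    baseline_frames: Optional[Sequence[int]] = None) -> PerfusionSeries:
    """Subtract the per-pixel mean over the baseline frames.

    Negative values are permitted (floating point).  Applying the removal
    twice is a no-op up to the noise in the baseline frames.
    """
    if baseline_frames is None:
        baseline_frames = detect_baseline_frames(series)
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ValueError("baseline frame set is empty")
    base = series.data[baseline_frames].mean(axis=0)
    out = series.with_data(series.data - base[np.newaxis])
    out.pd_frames = series.pd_frames
    return out
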