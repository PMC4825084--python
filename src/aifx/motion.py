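"""Motion correction of the perfusion series.

Cardiac and respiratory motion displace the heart between frames.  Frames
are registered to a common reference — the frame of maximal total intensity,
near the LV bolus peak, which offers the most stable anatomy — by composing
pairwise registrations between consecutive frames; adjacent frames have
similar contrast, which sidesteps the brightness-constancy violation caused
by contrast wash-in.

Each pairwise step estimates a rigid translation by subpixel phase
correlation on Gaussian-smoothed frames; composing the chain accumulates a
small random-walk drift, which a second pass of direct phase correlation
against the (aligned) reference frame removes.  An optional non-rigid
refinement adds an iterative Lucas-Kanade optical-flow field on the rigidly
aligned frames; it is off by default because bolus wash-in violates
brightness constancy inside the chambers and the flow there is spurious.
Returned displacement fields map corrected coordinates to original
coordinates, so warping the original frame by the field reproduces the
corrected frame.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.registration import optical_flow_ilk, phase_cross_correlation

from .io import PerfusionSeries

__all__ = ["register_series", "reference_frame_index", "mean_translations"]


def reference_frame_index(series: PerfusionSeries) -> int:
    """Index of the frame with maximal total intensity (near the LV peak)."""
    return int(np.argmax(series.data.sum(axis=(1, 2))))


def _warp(frame: np.ndarray, field: np.ndarray) -> np.ndarray:
    H, W = frame.shape
    yy, xx = np.mgrid[:H, :W].astype(float)
    return map_coordinates(frame, [yy + field[0], xx + field[1]], order=1, mode="nearest")


def register_series(
    series: PerfusionSeries,
    sigma_px: float = 1.0,
    reference: Optional[int] = None,
    refine_nonrigid: bool = False,
    n_refine: int = 2,
) -> tuple[PerfusionSeries, np.ndarray]:
    """Register every frame of a series to a common reference frame.

    Parameters
    ----------
    sigma_px:
        Gaussian pre-smoothing applied before motion estimation (optical
        flow assumes smooth gradients).
    reference:
        Reference frame index; ``None`` selects the maximal-intensity frame.
    refine_nonrigid:
        Add an optical-flow refinement on top of the rigid stage.

    Returns
    -------
    (corrected series, fields):
        ``fields`` has shape (T, 2, H, W); ``fields[i]`` maps corrected
        coordinates of frame ``i`` to its original coordinates.

    Degenerate (constant) frames cannot be registered; the identity field is
    returned for them with a warning.
    """
    T, H, W = series.data.shape
    ref = reference_frame_index(series) if reference is None else int(reference)
    sm = np.stack([gaussian_filter(f, sigma_px) for f in series.data]) if sigma_px > 0 else series.data

    degenerate = np.ptp(series.data, axis=(1, 2)) <= 1e-12

    # pairwise rigid translations between consecutive frames
    pair_shift = np.zeros((T, 2))  # shift of frame i relative to frame i+1 ... see below
    for i in range(T - 1):
        if degenerate[i] or degenerate[i + 1]:
            warnings.warn(f"degenerate frame at index {i} or {i + 1}; skipping pairwise step")
            continue
        d, _, _ = phase_cross_correlation(sm[i + 1], sm[i], upsample_factor=20,
                                          normalization=None)
        # returned d is the shift applying to frame i+1's content; the field
        # convention frame_i(x + w) ~= frame_{i+1}(x) needs w = -d
        pair_shift[i] = -d

    # compose rigid translations out to the reference frame
    rigid = np.zeros((T, 2))
    for i in range(ref - 1, -1, -1):
        rigid[i] = rigid[i + 1] + pair_shift[i]
    for i in range(ref + 1, T):
        rigid[i] = rigid[i - 1] - pair_shift[i - 1]

    # direct refinement against the reference removes chain drift; the
    # residual after the chain is small, so large apparent corrections are
    # false matches of dissimilar contrast states and are rejected
    ref_sm = sm[ref]
    max_residual = 1.5  # px
    for _ in range(n_refine):
        for i in range(T):
            if i == ref or degenerate[i]:
                continue
            moved = nd_shift_frame(sm[i], rigid[i])
            d, _, _ = phase_cross_correlation(ref_sm, moved, upsample_factor=20,
                                              normalization=None)
            if np.abs(d).max() <= max_residual:
                rigid[i] += -d

    fields = np.zeros((T, 2, H, W))
    corrected = np.empty_like(series.data)
    for i in range(T):
        field = np.zeros((2, H, W))
        field[0] += rigid[i, 0]
        field[1] += rigid[i, 1]
        if refine_nonrigid and not degenerate[i] and i != ref:
            moved = _warp(sm[i], field)
            v, u = optical_flow_ilk(ref_sm, moved, radius=7, gaussian=True)
            flow = np.stack([gaussian_filter(v, 2.0), gaussian_filter(u, 2.0)])
            # rigid part is spatially constant, so the exact composition
            # reduces to a sum of the two fields
            field = field + flow
        fields[i] = field
        corrected[i] = series.data[i] if i == ref else _warp(series.data[i], field)
    return series.with_data(corrected), fields


def nd_shift_frame(frame: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Apply a constant displacement field w (corrected -> original)."""
    H, W = frame.shape
    yy, xx = np.mgrid[:H, :W].astype(float)
    return map_coordinates(frame, [yy + w[0], xx + w[1]], order=1, mode="nearest")


def mean_translations(fields: np.ndarray, weight: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame mean displacement vector, optionally weighted by a mask/map.

    Useful to summarise a recovered field as a rigid translation estimate.
    """
    T = fields.shape[0]
    out = np.zeros((T, 2))
    if weight is None:
        w = np.ones(fields.shape[2:])
    else:
        w = np.asarray(weight, dtype=float)
    ws = w.sum()
    for i in range(T):
        out[i, 0] = (fields[i, 0] * w).sum() / ws
        out[i, 1] = (fields[i, 1] * w).sum() / ws
    return out
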