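"""Ventricular pixel detection by ICA source separation and correlation maps.

The pixel curves inside the candidate ventricle regions are modelled as
mixtures of two independent temporal sources — the RV and LV contrast
transits.  FastICA (fixed-point, whitened) extracts the two components;
each is sign-flipped so its peak is positive and rescaled to unit maximum.
Every pixel in the heart bounding box is then Pearson-correlated with both
sources at zero lag; pixels whose best correlation exceeds 0.7 are labelled
with that source's chamber, the rest become background.  The source peaking
first is the RV — contrast reaches the RV before the LV.

Papillary-muscle pixels, whose dim dynamics still track the LV curve, are
typically labelled LV at this stage; they are excluded later by the
bright-pixel AIF threshold.

Decorrelation-based separation cannot fully unmix the two transits: the RV
and LV bolus curves overlap in time and are therefore correlated, while ICA
constrains its outputs to be uncorrelated, leaving a residual mixing
ambiguity.  A bolus-model refinement (on by default) resolves it by
re-fitting all candidate pixel curves as non-negative mixtures of two
gamma-variate transits, seeded from the ICA components; the refined sources
are the fitted transits.  When the refined model explains the data poorly —
curves far from first-pass morphology — the raw ICA components are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .bolus import fit_gamma_shape, gamma_variate
from .heartdetect import HeartBox, RegionCandidate
from .io import PerfusionSeries

BACKGROUND, RV, LV = 0, 1, 2
CORR_THRESHOLD = 0.7

__all__ = [
    "VentricleMaps",
    "ICAError",
    "AmbiguousChambersError",
    "ica_sources",
    "classify_pixels",
    "BACKGROUND", "RV", "LV",
]


class ICAError(RuntimeError):
    """Source separation failed."""


class AmbiguousChambersError(ICAError):
    """The two sources peak simultaneously; RV/LV cannot be told apart."""


@dataclass
class VentricleMaps:
    """Per-pixel chamber labels inside the heart box plus the source curves."""

    labels: np.ndarray          # H x W, values BACKGROUND / RV / LV (0 outside box)
    rv_source: np.ndarray       # unit-peak source curve, length T
    lv_source: np.ndarray
    times: np.ndarray
    corr_rv: np.ndarray         # H x W correlation maps (0 outside box)
    corr_lv: np.ndarray
    box: HeartBox

    @property
    def rv_mask(self) -> np.ndarray:
        return self.labels == RV

    @property
    def lv_mask(self) -> np.ndarray:
        return self.labels == LV


def _canonicalize(source: np.ndarray) -> np.ndarray:
    s = source.copy()
    if abs(s.min()) > abs(s.max()):
        s = -s
    peak = s.max()
    if peak <= 0:
        raise ICAError("degenerate ICA source (non-positive peak)")
    return s / peak


def _joint_bolus_refine(times: np.ndarray, X: np.ndarray,
                        sources: tuple[np.ndarray, np.ndarray],
                        max_rel_residual: float = 0.2):
    """Refit pixel curves as non-negative mixtures of two gamma-variate transits.

    Shape parameters (onset, alpha, beta) of both transits are optimised
    jointly; per-pixel amplitudes are solved linearly at each step.  Returns
    the two unit-peak fitted transits, or ``None`` when the bolus model
    explains less than ``1 - max_rel_residual`` of the data (non-first-pass
    morphology: keep the ICA components instead).
    """
    init = np.concatenate([fit_gamma_shape(times, s) for s in sources])

    def model(theta):
        return np.stack([
            gamma_variate(times, theta[0], 1.0, theta[1], theta[2]),
            gamma_variate(times, theta[3], 1.0, theta[4], theta[5]),
        ], axis=1)

    def resid(theta):
        S = model(theta)
        C, *_ = np.linalg.lstsq(S, X, rcond=None)
        return (S @ np.clip(C, 0.0, None) - X).ravel()

    lb = [times[0] - 5.0, 0.5, 0.1] * 2
    ub = [float(times[-1]), 10.0, 10.0] * 2
    try:
        res = least_squares(resid, x0=np.clip(init, lb, ub), bounds=(lb, ub),
                            method="trf", max_nfev=200)
    except Exception:
        return None
    rel = np.sqrt(2 * res.cost) / max(np.linalg.norm(X), 1e-12)
    if rel > max_rel_residual:
        return None
    S = model(res.x)
    peaks = S.max(axis=0)
    if np.any(peaks <= 0):
        return None
    S = S / peaks
    return S[:, 0], S[:, 1]


def ica_sources(series: PerfusionSeries, regions: Sequence[RegionCandidate],
                seed: int = 0, max_retries: int = 5,
                refine: str = "bolus") -> tuple[np.ndarray, np.ndarray]:
    """Extract two independent temporal sources from candidate-region pixels.

    The T x n pixel-curve matrix of all region pixels feeds a two-component
    FastICA; sources are canonicalised to positive unit peak and, with
    ``refine="bolus"`` (the default), cleaned up by the joint two-transit
    gamma-variate fit.  On non-convergence the decomposition is retried
    with fresh seeds up to ``max_retries`` times before falling back, with
    a warning, to the two candidate-region mean curves.
    """
    union = np.zeros(series.frame_shape, dtype=bool)
    for r in regions:
        union |= r.mask
    X = series.data[:, union]  # T x n_pixels
    if X.shape[1] < 2:
        raise ICAError("need at least 2 pixels for source separation")

    raw = None
    for attempt in range(max_retries):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(n_components=2, random_state=seed + attempt,
                          whiten="unit-variance", max_iter=500, tol=1e-6)
            try:
                S = ica.fit_transform(X)  # T x 2 temporal sources
            except Exception:
                continue
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            try:
                raw = (_canonicalize(S[:, 0]), _canonicalize(S[:, 1]))
                break
            except ICAError:
                continue

    if raw is None:
        warnings.warn("ICA did not converge; falling back to candidate mean curves")
        if len(regions) < 2:
            raise ICAError("ICA failed and fewer than 2 regions for fallback")
        raw = (_canonicalize(regions[0].curve - regions[0].curve.min()),
               _canonicalize(regions[1].curve - regions[1].curve.min()))

    if refine == "bolus":
        refined = _joint_bolus_refine(series.frame_times, X, raw)
        if refined is not None:
            return refined
    return raw


def _pixel_correlations(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X (T x n) with s; 0 where undefined."""
    Xc = X - X.mean(axis=0)
    sc = s - s.mean()
    num = Xc.T @ sc
    den = np.sqrt((Xc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def classify_pixels(series: PerfusionSeries, box: HeartBox,
                    sources: tuple[np.ndarray, np.ndarray],
                    corr_threshold: float = CORR_THRESHOLD) -> VentricleMaps:
    """Label every heart-box pixel RV, LV or background by source correlation.

    A pixel joins the chamber of the source it correlates with best, if
    that correlation exceeds ``corr_threshold``; flat (zero-variance) pixel
    curves get correlation 0 and stay background.  The earlier-peaking
    source is the RV.
    """
    s0, s1 = np.asarray(sources[0], dtype=float), np.asarray(sources[1], dtype=float)
    p0, p1 = int(np.argmax(s0)), int(np.argmax(s1))
    if p0 == p1:
        raise AmbiguousChambersError("sources peak at the same time")
    rv_source, lv_source = (s0, s1) if p0 < p1 else (s1, s0)

    sl = box.slices()
    sub = series.data[:, sl[0], sl[1]]
    T, h, w = sub.shape
    X = sub.reshape(T, -1)
    r_rv = _pixel_correlations(X, rv_source).reshape(h, w)
    r_lv = _pixel_correlations(X, lv_source).reshape(h, w)

    labels_box = np.zeros((h, w), dtype=np.int8)
    best = np.maximum(r_rv, r_lv)
    labels_box[(best > corr_threshold) & (r_rv >= r_lv)] = RV
    labels_box[(best > corr_threshold) & (r_lv > r_rv)] = LV

    H, W = series.frame_shape
    labels = np.zeros((H, W), dtype=np.int8)
    corr_rv = np.zeros((H, W))
    corr_lv = np.zeros((H, W))
    labels[sl] = labels_box
    corr_rv[sl] = r_rv
    corr_lv[sl] = r_lv
    return VentricleMaps(labels=labels, rv_source=rv_source, lv_source=lv_source,
                         times=series.frame_times.copy(), corr_rv=corr_rv,
                         corr_lv=corr_lv, box=box)
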