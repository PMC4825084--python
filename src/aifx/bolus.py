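"""Gamma-variate bolus model shared by the phantom and source refinement.

The first pass of a contrast bolus through a cardiac chamber is well
described by a gamma-variate: zero before the onset, a skewed peak, and an
exponential tail.  The parameterisation here is normalised so the curve's
maximum equals the amplitude ``A`` exactly at ``t = t0 + alpha * beta``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["gamma_variate", "fit_gamma_shape"]


def gamma_variate(t, t0: float, A: float, alpha: float, beta: float) -> np.ndarray:
    """Normalised gamma-variate bolus curve.

    ``A * ((t - t0) / (alpha * beta))**alpha * exp(alpha - (t - t0)/beta)``,
    zero for t <= t0.  The normalisation makes the maximum exactly ``A`` at
    ``t = t0 + alpha * beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    x = dt[pos] / (alpha * beta)
    out[pos] = A * np.power(x, alpha) * np.exp(alpha - dt[pos] / beta)
    return out if out.ndim else float(out)


def fit_gamma_shape(t: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Least-squares gamma-variate shape (t0, alpha, beta) of a bolus curve.

    Used to seed the joint two-transit fit; falls back to a crude moment
    guess when the fit does not converge.
    """
    pk = int(np.argmax(s))
    A0 = float(s[pk])
    above = np.flatnonzero(s > 0.05 * A0)
    t00 = float(t[above[0]]) if above.size else float(t[0])
    beta0 = max((t[pk] - t00) / 3.0, 0.3)

    def f(tt, A, t0, alpha, beta):
        return gamma_variate(tt, t0, A, alpha, beta)

    try:
        p, _ = curve_fit(
            f, t, s, p0=[A0, t00, 3.0, beta0],
            bounds=([0, t[0] - 5, 0.5, 0.1], [10 * max(A0, 1e-6), t[pk], 10, 10]),
            maxfev=5000,
        )
        return float(p[1]), float(p[2]), float(p[3])
    except Exception:
        return t00, 3.0, beta0
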