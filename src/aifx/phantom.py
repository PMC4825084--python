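"""Synthetic dynamic perfusion phantom with exported ground truth.

Emulates a first-pass contrast-enhanced perfusion series: a gamma-variate
bolus transits the RV first and the LV after a delay, the myocardium
enhances later and weakly (the convolution of the LV bolus with a Fermi
impulse response scaled by the sector flow), dark papillary blobs sit
inside the LV cavity, a smooth multiplicative coil-shading field and an
additive baseline offset corrupt the intensities, frames move rigidly (or
with an optional smooth elastic warp), and Gaussian (optionally Rician)
noise is added.  Proton-density frames encode the shading field alone.

Every corrupting factor is exported as ground truth (true AIF, masks,
displacements, flows, shading), so each pipeline stage can be tested
against what it should recover.  Defaults mimic the dedicated AIF series
geometry (48 x 64 matrix, 60 frames at a 1 s R-R interval); the myocardial
series is the same spec at 192 x 256.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates, shift as nd_shift

from .bolus import gamma_variate
from .io import PerfusionSeries
from .mbf import forward_tissue

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "gamma_variate",
    "generate_phantom",
    "make_pd_frames",
    "random_spec",
]


@dataclass
class PhantomSpec:
    """Full description of one synthetic perfusion study.

    Geometry is in pixels on an (H, W) grid; times in seconds; intensities
    in arbitrary units; flows in ml/g/min.
    """

    shape: tuple[int, int] = (48, 64)
    n_frames: int = 60
    rr_interval: float = 1.0

    rv_center: tuple[float, float] = (24.0, 16.0)
    rv_radius: float = 7.5
    lv_center: tuple[float, float] = (24.0, 38.0)
    lv_radius: float = 7.5
    myo_thickness: float = 3.5
    papillary: tuple = (((26.5, 35.0), 1.3), ((21.5, 39.5), 1.2))
    papillary_frac: float = 0.15
    pv_rim_width: float = 0.0       # >0 adds a partial-volume rim ring on the LV edge
    pv_rim_frac: float = 0.5        # blood weight of rim pixels

    body_amp: float = 25.0          # chest/body tissue signal visible pre-contrast
    rv_amp: float = 80.0
    lv_amp: float = 100.0
    bolus_onset: float = 4.0        # RV onset t0
    bolus_alpha: float = 2.5
    bolus_beta: float = 1.8
    rv_lv_delay: float = 4.0

    flows: tuple = (1.1,) * 6       # per-sector MBF, ml/g/min
    fermi_k: float = 0.15           # 1/s
    fermi_tau: float = 3.0          # s

    shading_coeffs: Optional[np.ndarray] = None  # c[i,j] on (row/H)^i (col/W)^j
    baseline: float = 40.0
    pd_amplitude: float = 200.0

    motion_amplitude_px: float = 1.5
    motion_model: str = "rigid"     # 'rigid' | 'elastic'
    motion_schedule: Optional[np.ndarray] = None  # (T, 2) (drow, dcol)

    noise_sigma: float = 2.0
    noise_model: str = "gaussian"   # 'gaussian' | 'rician'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if self.rv_radius <= 0 or self.lv_radius <= 0:
            raise ValueError("radii must be positive")
        if self.rv_lv_delay <= 0:
            raise ValueError("RV-to-LV delay must be positive (RV peaks first)")
        H, W = self.shape
        for (cy, cx), r in (
            (self.rv_center, self.rv_radius),
            (self.lv_center, self.lv_radius + self.myo_thickness),
        ):
            if cy - r < 0 or cy + r > H or cx - r < 0 or cx + r > W:
                raise ValueError("disc (with annulus) extends outside the grid")
        for (cy, cx), r in self.papillary:
            d = np.hypot(cy - self.lv_center[0], cx - self.lv_center[1])
            if d + r >= self.lv_radius:
                raise ValueError("papillary blob not strictly inside the LV disc")
        if self.shading_coeffs is None:
            self.shading_coeffs = np.array([[1.0, 0.35], [-0.25, 0.0]])
        else:
            self.shading_coeffs = np.atleast_2d(np.asarray(self.shading_coeffs, dtype=float))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.rr_interval

    def lv_curve(self, t) -> np.ndarray:
        return gamma_variate(t, self.bolus_onset + self.rv_lv_delay,
                             self.lv_amp, self.bolus_alpha, self.bolus_beta)

    def rv_curve(self, t) -> np.ndarray:
        return gamma_variate(t, self.bolus_onset, self.rv_amp,
                             self.bolus_alpha, self.bolus_beta)

    def shading_field(self) -> np.ndarray:
        H, W = self.shape
        yy = (np.arange(H) / H)[:, None]
        xx = (np.arange(W) / W)[None, :]
        f = np.zeros((H, W))
        for i in range(self.shading_coeffs.shape[0]):
            for j in range(self.shading_coeffs.shape[1]):
                c = self.shading_coeffs[i, j]
                if c != 0:
                    f += c * yy**i * xx**j
        if np.any(f <= 0):
            raise ValueError("shading field must be strictly positive")
        return f

    def to_json(self) -> str:
        d = asdict(self)
        d["shading_coeffs"] = np.asarray(self.shading_coeffs).tolist()
        if self.motion_schedule is not None:
            d["motion_schedule"] = np.asarray(self.motion_schedule).tolist()
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for key in ("shape", "rv_center", "lv_center", "flows"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("papillary"):
            d["papillary"] = tuple((tuple(c), r) for c, r in d["papillary"])
        if d.get("shading_coeffs") is not None:
            d["shading_coeffs"] = np.asarray(d["shading_coeffs"], dtype=float)
        if d.get("motion_schedule") is not None:
            d["motion_schedule"] = np.asarray(d["motion_schedule"], dtype=float)
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth exported alongside a generated phantom series."""

    aif_times: np.ndarray            # frame times, s
    aif_values: np.ndarray           # noiseless LV chamber signal at frame times
    rv_mask: np.ndarray
    lv_mask: np.ndarray              # cavity excluding papillary blobs (and any PV rim)
    myo_mask: np.ndarray
    papillary_mask: np.ndarray
    rim_mask: np.ndarray
    displacements: np.ndarray        # (T, 2) true per-frame (drow, dcol)
    flows: np.ndarray                # per-sector ml/g/min
    shading: np.ndarray
    pd_frames: list
    spec: PhantomSpec

    def analytic_aif(self, dt: float = 0.5):
        """True AIF evaluated analytically on a uniform grid (default 0.5 s)."""
        from .aif import AIFCurve

        t = np.arange(0.0, self.aif_times[-1] + 1e-9, dt)
        return AIFCurve(times=t, values=self.spec.lv_curve(t))

    def heart_mask(self) -> np.ndarray:
        return self.rv_mask | self.lv_mask | self.myo_mask | self.papillary_mask | self.rim_mask

    def mask_in_frame(self, mask: np.ndarray, frame_index: int) -> np.ndarray:
        """A truth mask mapped into the coordinates of a given frame.

        A motion-corrected series lives in the coordinates of its reference
        frame, which is displaced from the truth-mask frame by that frame's
        true displacement; this shifts the mask accordingly (nearest pixel).
        """
        dy, dx = np.round(self.displacements[frame_index]).astype(int)
        out = np.zeros_like(mask)
        H, W = mask.shape
        rr, cc = np.nonzero(mask)
        rr2, cc2 = rr + dy, cc + dx
        keep = (rr2 >= 0) & (rr2 < H) & (cc2 >= 0) & (cc2 < W)
        out[rr2[keep], cc2[keep]] = True
        return out


def _disc(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _make_motion(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.motion_schedule is not None:
        sched = np.asarray(spec.motion_schedule, dtype=float)
        if sched.shape != (spec.n_frames, 2):
            raise ValueError("motion_schedule must have shape (T, 2)")
        return sched
    a = spec.motion_amplitude_px
    if a == 0:
        return np.zeros((spec.n_frames, 2))
    t = spec.frame_times
    # respiratory-like sinusoid plus a small random drift, amplitude-bounded
    period = rng.uniform(4.0, 7.0)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    amp = rng.uniform(0.5 * a, a, size=2)
    sched = np.stack(
        [amp[i] * np.sin(2 * np.pi * t / period + phase[i]) for i in range(2)], axis=1
    )
    return sched


def _sector_index(spec: PhantomSpec, rr, cc) -> np.ndarray:
    ang = np.mod(np.arctan2(-(rr - spec.lv_center[0]), cc - spec.lv_center[1]), 2 * np.pi)
    n = len(spec.flows)
    return np.minimum((ang / (2 * np.pi) * n).astype(int), n - 1)


def make_pd_frames(spec: PhantomSpec, rng: Optional[np.random.Generator] = None) -> list:
    """Two proton-density frames: shading field times a PD amplitude + noise."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    shading = spec.shading_field()
    frames = []
    for _ in range(2):
        f = spec.pd_amplitude * shading
        if spec.noise_sigma > 0:
            f = f + rng.normal(0, spec.noise_sigma, size=f.shape)
        frames.append(f)
    return frames


def generate_phantom(spec: PhantomSpec) -> tuple[PerfusionSeries, PhantomTruth]:
    """Generate a perfusion series and its ground truth from a spec.

    Frame synthesis order mirrors acquisition physics: the moving anatomy is
    shifted first, then multiplied by the static coil-shading field, offset
    by the baseline and corrupted by noise.  With zero noise/motion/shading
    the mean over the true LV mask reproduces the analytic AIF exactly.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    T = spec.n_frames
    t = spec.frame_times

    lv_disc = _disc(spec.shape, spec.lv_center, spec.lv_radius)
    rv_mask = _disc(spec.shape, spec.rv_center, spec.rv_radius) & ~lv_disc
    myo_outer = _disc(spec.shape, spec.lv_center, spec.lv_radius + spec.myo_thickness)
    myo_mask = myo_outer & ~lv_disc & ~rv_mask
    pap_mask = np.zeros((H, W), dtype=bool)
    for center, radius in spec.papillary:
        pap_mask |= _disc(spec.shape, center, radius)
    pap_mask &= lv_disc
    rim_mask = np.zeros((H, W), dtype=bool)
    if spec.pv_rim_width > 0:
        inner = _disc(spec.shape, spec.lv_center, spec.lv_radius - spec.pv_rim_width)
        rim_mask = lv_disc & ~inner & ~pap_mask
    lv_mask = lv_disc & ~pap_mask & ~rim_mask

    # surrounding body tissue: visible before contrast, moves with the heart
    yy, xx = np.mgrid[:H, :W].astype(float)
    body = (
        ((yy - H / 2) / (0.40 * H)) ** 2
        + ((xx - W / 2) / (0.44 * W)) ** 2
    ) <= 1.0
    body &= ~(rv_mask | lv_disc | myo_mask)
    body_texture = spec.body_amp * (
        1.0 + 0.25 * np.sin(2 * np.pi * 3 * xx / W) * np.sin(2 * np.pi * 2 * yy / H)
    )

    rv_c = spec.rv_curve(t)
    lv_c = spec.lv_curve(t)
    pap_c = spec.papillary_frac * lv_c

    # myocardial curves: Fermi-convolved LV bolus on a fine grid, sampled at t
    t_dense = np.arange(0.0, t[-1] + spec.rr_interval, 0.25)
    aif_dense = spec.lv_curve(t_dense)
    myo_curves = []
    for F in spec.flows:
        tis = forward_tissue(t_dense, aif_dense, F, spec.fermi_k, spec.fermi_tau)
        myo_curves.append(np.interp(t, t_dense, tis))
    myo_curves = np.asarray(myo_curves)

    clean = np.zeros((T, H, W))
    clean[:, body] = body_texture[body][None, :]
    clean[:, rv_mask] = rv_c[:, None]
    clean[:, lv_mask] = lv_c[:, None]
    clean[:, pap_mask] = pap_c[:, None]
    rr_m, cc_m = np.nonzero(myo_mask)
    sect = _sector_index(spec, rr_m, cc_m)
    clean[:, rr_m, cc_m] = myo_curves[sect].T
    if rim_mask.any():
        rr_r, cc_r = np.nonzero(rim_mask)
        sect_r = _sector_index(spec, rr_r, cc_r)
        w = spec.pv_rim_frac
        clean[:, rr_r, cc_r] = (w * lv_c[:, None] + (1 - w) * myo_curves[sect_r].T)

    displacements = _make_motion(spec, rng)
    shading = spec.shading_field()
    data = np.empty_like(clean)
    for i in range(T):
        frame = clean[i]
        dy, dx = displacements[i]
        if dy != 0 or dx != 0:
            frame = nd_shift(frame, (dy, dx), order=1, mode="constant", cval=0.0)
        if spec.motion_model == "elastic" and spec.motion_amplitude_px > 0:
            frame = _elastic_warp(frame, i, spec)
        data[i] = frame * shading + spec.baseline

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0, spec.noise_sigma, size=data.shape)
        elif spec.noise_model == "rician":
            n1 = rng.normal(0, spec.noise_sigma, size=data.shape)
            n2 = rng.normal(0, spec.noise_sigma, size=data.shape)
            data = np.sqrt((data + n1) ** 2 + n2**2)
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")

    pd_frames = make_pd_frames(spec, rng)
    series = PerfusionSeries(data=data, frame_times=t, pd_frames=pd_frames,
                             kind="aif" if max(H, W) <= 128 else "myocardial")
    truth = PhantomTruth(
        aif_times=t, aif_values=lv_c, rv_mask=rv_mask, lv_mask=lv_mask,
        myo_mask=myo_mask, papillary_mask=pap_mask, rim_mask=rim_mask,
        displacements=displacements, flows=np.asarray(spec.flows, dtype=float),
        shading=shading, pd_frames=pd_frames, spec=spec,
    )
    return series, truth


def _elastic_warp(frame: np.ndarray, i: int, spec: PhantomSpec) -> np.ndarray:
    """Smooth low-frequency sinusoidal warp, amplitude-bounded by the spec."""
    H, W = frame.shape
    yy, xx = np.mgrid[:H, :W].astype(float)
    a = 0.3 * spec.motion_amplitude_px
    ph = 2 * np.pi * i / spec.n_frames
    dy = a * np.sin(2 * np.pi * xx / W + ph)
    dx = a * np.sin(2 * np.pi * yy / H - ph)
    return map_coordinates(frame, [yy + dy, xx + dx], order=1, mode="nearest")


def random_spec(seed: int, shape: tuple[int, int] = (48, 64), **overrides) -> PhantomSpec:
    """A randomised but physiologically plausible phantom spec.

    Geometry, bolus timing/shape, flows, noise and motion are jittered
    within ranges that keep the study realistic; used for the randomized
    validation batteries.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    scale = min(H, W) / 48.0
    lv_r = rng.uniform(6.0, 8.5) * scale
    myo_t = rng.uniform(3.0, 4.0) * scale
    lv_cy = H / 2 + rng.uniform(-3, 3) * scale
    lv_cx = W * 0.6 + rng.uniform(-3, 3) * scale
    lv_cy = np.clip(lv_cy, lv_r + myo_t + 1, H - lv_r - myo_t - 1)
    lv_cx = np.clip(lv_cx, lv_r + myo_t + 1, W - lv_r - myo_t - 1)
    rv_r = rng.uniform(6.5, 9.0) * scale
    rv_cx = lv_cx - (lv_r + myo_t + rv_r + rng.uniform(0.0, 2.0) * scale)
    rv_cy = lv_cy + rng.uniform(-2, 2) * scale
    rv_cx = np.clip(rv_cx, rv_r + 1, W - rv_r - 1)
    rv_cy = np.clip(rv_cy, rv_r + 1, H - rv_r - 1)
    # two papillary blobs strictly inside the LV
    pap = []
    for _ in range(2):
        ang = rng.uniform(0, 2 * np.pi)
        pr = rng.uniform(1.0, 1.5) * scale
        d = rng.uniform(0.2, 0.6) * (lv_r - pr - 0.5)
        pap.append(((lv_cy + d * np.sin(ang), lv_cx + d * np.cos(ang)), pr))
    params = dict(
        shape=shape,
        rv_center=(float(rv_cy), float(rv_cx)), rv_radius=float(rv_r),
        lv_center=(float(lv_cy), float(lv_cx)), lv_radius=float(lv_r),
        myo_thickness=float(myo_t), papillary=tuple(pap),
        rv_amp=float(rng.uniform(70, 90)), lv_amp=float(rng.uniform(90, 110)),
        bolus_onset=float(rng.uniform(3.0, 6.0)),
        bolus_alpha=float(rng.uniform(2.0, 3.0)),
        bolus_beta=float(rng.uniform(1.5, 2.2)),
        rv_lv_delay=float(rng.uniform(3.0, 5.0)),
        noise_sigma=float(rng.uniform(1.5, 2.5)),
        motion_amplitude_px=float(rng.uniform(0.5, 2.0)),
        shading_coeffs=np.array([[1.0, rng.uniform(0.2, 0.45)],
                                 [rng.uniform(-0.35, -0.15), 0.0]]),
        seed=int(seed),
    )
    params.update(overrides)
    return PhantomSpec(**params)
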