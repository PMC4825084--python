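"""End-to-end AIF extraction pipeline.

Stage order is fixed: motion correction -> heart region detection ->
intensity correction (coil shading + baseline removal) -> ICA ventricular
pixel classification -> bright-pixel AIF extraction -> timing points ->
quality metrics.  Each stage failure is logged with its stage name and
surfaced as a distinct exit code so over-segmentation and ICA separation
failures can be told apart downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import aif as aifmod
from . import heartdetect, icaclassify, intensity, io, motion

log = logging.getLogger("aifx")

# distinct exit codes per failure mode
EXIT_OK = 0
EXIT_IO = 2
EXIT_EMPTY_CANDIDATES = 3
EXIT_ICA_FAILURE = 4
EXIT_TIMING_FAILURE = 5

__all__ = [
    "PipelineConfig", "PipelineResult", "StageError", "run_pipeline",
    "EXIT_OK", "EXIT_IO", "EXIT_EMPTY_CANDIDATES", "EXIT_ICA_FAILURE",
    "EXIT_TIMING_FAILURE",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit code."""

    def __init__(self, stage: str, exit_code: int, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.exit_code = exit_code
        self.cause = cause


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with the published defaults."""

    # motion
    motion_enabled: bool = True
    motion_sigma_px: float = 1.0
    motion_reference: Optional[int] = None   # None = auto (max-intensity frame)
    motion_refine_nonrigid: bool = False
    # heart detection
    detect_k_sigma_aif: float = 1.0
    detect_k_sigma_myo: float = 2.0
    detect_corr_merge: float = 0.75
    detect_min_px_aif: int = 4
    detect_min_px_myo: int = 16
    detect_box_margin: float = 0.25
    # intensity
    intensity_enabled: bool = True
    intensity_poly_order: int = 3
    # ICA
    ica_corr_threshold: float = 0.7
    ica_seed: int = 0
    ica_max_retries: int = 5
    # AIF extraction
    aif_percentile: float = 75.0
    aif_threshold_mode: str = "range"
    rr_interval: float = 1.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a config from JSON or TOML; unknown keys are rejected."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        valid = set(cls().__dataclass_fields__)
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    aif: aifmod.AIFCurve
    timing: aifmod.TimingPoints
    metrics: aifmod.AIFMetrics
    maps: icaclassify.VentricleMaps
    box: heartdetect.HeartBox
    corrected: io.PerfusionSeries
    displacement_fields: Optional[np.ndarray] = None
    reference_index: Optional[int] = None  # frame whose coordinates the output uses

    def metrics_dict(self) -> dict:
        return {
            "pv_au": self.metrics.pv,
            "ttp_s": self.metrics.ttp,
            "fwhm_s": self.metrics.fwhm,
            "upslope_au_per_s": self.metrics.upslope,
            "m_value_au_per_s2": self.metrics.m_value,
            "fwhm_clipped": self.metrics.fwhm_clipped,
        }


def run_pipeline(series: io.PerfusionSeries,
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full AIF extraction pipeline on an in-memory series."""
    cfg = config or PipelineConfig()

    fields = None
    ref_index = None
    if cfg.motion_enabled:
        log.info("stage: motion correction")
        ref_index = (cfg.motion_reference if cfg.motion_reference is not None
                     else motion.reference_frame_index(series))
        series, fields = motion.register_series(
            series, sigma_px=cfg.motion_sigma_px, reference=ref_index,
            refine_nonrigid=cfg.motion_refine_nonrigid,
        )

    log.info("stage: heart region detection")
    try:
        sd = heartdetect.std_map(series)
        k = cfg.detect_k_sigma_aif if series.kind == "aif" else cfg.detect_k_sigma_myo
        min_px = cfg.detect_min_px_aif if series.kind == "aif" else cfg.detect_min_px_myo
        cands = heartdetect.threshold_candidates(sd, series, k_sigma=k, min_px=min_px)
        cands = heartdetect.filter_candidates(cands)
        cands = heartdetect.merge_similar(cands, series,
                                          corr_threshold=cfg.detect_corr_merge)
        first, second = heartdetect.vote_ventricles(cands, series.frame_shape)
        box = heartdetect.heart_box(first, second, series.frame_shape,
                                    margin=cfg.detect_box_margin)
    except (heartdetect.EmptyCandidateError,
            heartdetect.InsufficientCandidatesError) as e:
        log.error("heart detection failed: %s", e)
        raise StageError("heartdetect", EXIT_EMPTY_CANDIDATES, e) from e

    log.info("stage: intensity correction")
    if series.pd_frames:
        series = intensity.coil_correct(series, order=cfg.intensity_poly_order,
                                        heart_box=box, enabled=cfg.intensity_enabled)
    else:
        log.warning("no PD frames: coil shading correction skipped")
    series = intensity.remove_baseline(series)
    # candidate curves must reflect the corrected intensities for ICA
    for c in (first, second):
        c.curve = series.data[:, c.mask].mean(axis=1)

    log.info("stage: ICA ventricular pixel detection")
    try:
        sources = icaclassify.ica_sources(series, [first, second],
                                          seed=cfg.ica_seed,
                                          max_retries=cfg.ica_max_retries)
        maps = icaclassify.classify_pixels(series, box, sources,
                                           corr_threshold=cfg.ica_corr_threshold)
        if not maps.lv_mask.any():
            raise icaclassify.ICAError("no pixels classified as LV")
    except icaclassify.ICAError as e:
        log.error("ICA classification failed: %s", e)
        raise StageError("icaclassify", EXIT_ICA_FAILURE, e) from e

    log.info("stage: AIF extraction (q=%g)", cfg.aif_percentile)
    try:
        curve = aifmod.extract_aif(series, maps.lv_mask,
                                   percentile=cfg.aif_percentile,
                                   mode=cfg.aif_threshold_mode)
        tp = aifmod.timing_points(curve)
        curve.timing = tp
        metrics = aifmod.curve_metrics(curve, tp)
    except (aifmod.TimingError, aifmod.ExtractionError) as e:
        log.error("AIF timing/extraction failed: %s", e)
        raise StageError("aif", EXIT_TIMING_FAILURE, e) from e

    log.info("AIF extracted: threshold=%.4g, %d pixels, peak %.4g a.u.",
             curve.threshold, int(curve.pixel_mask.sum()), curve.values.max())
    return PipelineResult(aif=curve, timing=tp, metrics=metrics, maps=maps,
                          box=box, corrected=series, displacement_fields=fields,
                          reference_index=ref_index)


def write_outputs(result: PipelineResult, out_dir, qc: bool = True) -> dict:
    """Write curve CSV, timing JSON, metrics JSON and a QC overlay figure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["aif_csv"] = io.write_aif(result.aif, out_dir / "aif.csv")
    timing = {
        "baseline_time_s": result.timing.baseline_time,
        "start_time_s": result.timing.start_time,
        "peak_time_s": result.timing.peak_time,
    }
    (out_dir / "timing.json").write_text(json.dumps(timing, indent=2, sort_keys=True) + "\n")
    paths["timing_json"] = out_dir / "timing.json"
    (out_dir / "metrics.json").write_text(
        json.dumps(result.metrics_dict(), indent=2, sort_keys=True) + "\n")
    paths["metrics_json"] = out_dir / "metrics.json"
    if qc:
        paths["qc_png"] = _qc_figure(result, out_dir / "qc.png")
    return paths


def _qc_figure(result: PipelineResult, path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    mip = result.corrected.data.max(axis=0)
    axes[0].imshow(mip, cmap="gray")
    overlay = np.zeros(mip.shape + (4,))
    overlay[result.maps.rv_mask] = (0.2, 0.4, 1.0, 0.35)
    overlay[result.maps.lv_mask] = (1.0, 0.8, 0.1, 0.35)
    if result.aif.pixel_mask is not None:
        overlay[result.aif.pixel_mask] = (1.0, 0.1, 0.1, 0.8)
    axes[0].imshow(overlay)
    b = result.box
    axes[0].add_patch(plt.Rectangle((b.col0 - 0.5, b.row0 - 0.5), b.col1 - b.col0,
                                    b.row1 - b.row0, fill=False, color="lime"))
    axes[0].set_title("MIP + RV/LV labels + AIF pixels")
    axes[0].axis("off")
    axes[1].plot(result.aif.times, result.aif.values, "-", lw=1.5)
    for name, tval in (("baseline", result.timing.baseline_time),
                       ("start", result.timing.start_time),
                       ("peak", result.timing.peak_time)):
        axes[1].axvline(tval, ls="--", alpha=0.6)
        axes[1].text(tval, axes[1].get_ylim()[1] * 0.95, name, rotation=90,
                     va="top", fontsize=8)
    axes[1].set_xlabel("time (s)")
    axes[1].set_ylabel("signal (a.u.)")
    axes[1].set_title("AIF with timing points")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
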