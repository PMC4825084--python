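"""Reading and writing perfusion series and AIF curves.

The canonical in-memory representation is :class:`PerfusionSeries`: a
T x H x W floating-point intensity stack with per-frame acquisition times in
seconds.  Series are read from NIfTI-1 4-D volumes or classic single-frame
DICOM series and written back as NIfTI (optionally DICOM).  AIF curves go to
CSV with a JSON sidecar carrying provenance (threshold, pixel count, timing
points).

Conventions: arrays are 0-based, row-major, pixel-centre; masks are boolean
H x W arrays; time is always seconds internally.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

MIN_FRAMES = 10

__all__ = [
    "PerfusionSeries",
    "FormatError",
    "InsufficientDataError",
    "read_series",
    "write_series",
    "write_dicom_series",
    "write_aif",
    "read_aif",
]


class FormatError(ValueError):
    """Input file(s) do not form a valid perfusion series."""


class InsufficientDataError(FormatError):
    """Series has too few frames for dynamic analysis."""


@dataclass
class PerfusionSeries:
    """A dynamic perfusion image series, one frame per cardiac cycle.

    Parameters
    ----------
    data:
        Intensity stack of shape (T, H, W), floating point, arbitrary units.
    frame_times:
        Acquisition time of each frame in seconds, strictly increasing.
    pd_frames:
        Optional proton-density weighted frames (each H x W) acquired without
        saturation preparation; they encode the surface-coil sensitivity and
        drive shading correction.
    kind:
        ``"aif"`` for the low-resolution dedicated AIF series, ``"myocardial"``
        for the high-resolution series.  Controls detection thresholds.
    pixel_spacing:
        Optional (row, col) spacing in mm.
    """

    data: np.ndarray
    frame_times: np.ndarray
    pd_frames: Optional[list[np.ndarray]] = None
    kind: str = "aif"
    pixel_spacing: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected (T, H, W) stack, got shape {self.data.shape}")
        if self.data.shape[0] < MIN_FRAMES:
            raise InsufficientDataError(
                f"series has {self.data.shape[0]} frames; at least {MIN_FRAMES} required"
            )
        if self.frame_times.shape != (self.data.shape[0],):
            raise FormatError("frame_times length must equal number of frames")
        if not np.all(np.diff(self.frame_times) > 0):
            raise FormatError("frame_times must be strictly increasing")
        if self.kind not in ("aif", "myocardial"):
            raise ValueError(f"kind must be 'aif' or 'myocardial', got {self.kind!r}")
        if self.pd_frames is not None:
            self.pd_frames = [np.asarray(f, dtype=float) for f in self.pd_frames]
            for f in self.pd_frames:
                if f.shape != self.data.shape[1:]:
                    raise FormatError("PD frame shape must match series frame shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "PerfusionSeries":
        """Return a copy of this series with replaced intensity data."""
        return replace(self, data=np.asarray(data, dtype=float))


def _read_nifti(path: Path, kind: str, rr_interval: float) -> PerfusionSeries:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim == 4:
        # stored (x, y, z=1, t) -> (t, y, x)
        if arr.shape[2] != 1:
            raise FormatError("only single-slice 4-D volumes are supported")
        data = np.transpose(arr[:, :, 0, :], (2, 1, 0))
    elif arr.ndim == 3:
        data = np.transpose(arr, (2, 1, 0))
    else:
        raise FormatError(f"expected 3-D or 4-D NIfTI, got {arr.ndim}-D")
    times = np.arange(data.shape[0], dtype=float) * rr_interval
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]), float(zooms[0])) if len(zooms) >= 2 else None
    return PerfusionSeries(data, times, kind=kind, pixel_spacing=spacing)


def _read_dicom_dir(path: Path, kind: str, rr_interval: float) -> PerfusionSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ".ima", ""))
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no readable DICOM frames under {path}")

    def sort_key(ds):
        t = getattr(ds, "TriggerTime", None)
        if t is not None:
            return (0, float(t))
        at = getattr(ds, "AcquisitionTime", None)
        if at:
            return (1, _parse_dicom_time(str(at)))
        return (2, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    frames = []
    for ds in datasets:
        f = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(f * slope + intercept)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame shapes in DICOM series: {sorted(shapes)}")
    data = np.stack(frames)

    times = []
    for ds in datasets:
        t = getattr(ds, "TriggerTime", None)
        times.append(float(t) / 1000.0 if t is not None else np.nan)
    times_arr = np.asarray(times)
    if np.any(np.isnan(times_arr)) or not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(frames), dtype=float) * rr_interval
    else:
        times_arr = times_arr - times_arr[0]

    spacing = None
    ps = getattr(datasets[0], "PixelSpacing", None)
    if ps is not None:
        spacing = (float(ps[0]), float(ps[1]))
    return PerfusionSeries(data, times_arr, kind=kind, pixel_spacing=spacing)


def _parse_dicom_time(s: str) -> float:
    s = s.strip()
    h, m = int(s[0:2]), int(s[2:4])
    sec = float(s[4:]) if len(s) > 4 else 0.0
    return h * 3600 + m * 60 + sec


def read_series(path, kind: str = "aif", rr_interval: float = 1.0) -> PerfusionSeries:
    """Read a perfusion series from a NIfTI file or a DICOM directory.

    Frames are sorted by acquisition time.  When per-frame times are absent
    (NIfTI, or DICOM without usable time tags), ``frame_times`` is synthesised
    as ``index * rr_interval``.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path, kind, rr_interval)
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_nifti(path, kind, rr_interval)


def write_series(series: PerfusionSeries, path) -> Path:
    """Write a series as a NIfTI-1 4-D volume (x, y, 1, t)."""
    import nibabel as nib

    path = Path(path)
    arr = np.transpose(series.data, (2, 1, 0))[:, :, np.newaxis, :]
    affine = np.eye(4)
    if series.pixel_spacing is not None:
        affine[0, 0] = series.pixel_spacing[1]
        affine[1, 1] = series.pixel_spacing[0]
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.to_filename(str(path))
    return path


def write_dicom_series(series: PerfusionSeries, out_dir) -> list[Path]:
    """Write a series as classic single-frame DICOM files (secondary capture).

    Intensities are linearly quantised to uint16; TriggerTime carries the
    frame time in ms so reading sorts frames correctly even if file order is
    shuffled.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = float(series.data.min()), float(series.data.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for i in range(series.n_frames):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.TriggerTime = f"{series.frame_times[i] * 1000.0:.6g}"
        if series.pixel_spacing is not None:
            ds.PixelSpacing = [f"{series.pixel_spacing[0]:.8g}",
                               f"{series.pixel_spacing[1]:.8g}"]
        frame = np.round((series.data[i] - lo) * scale).astype(np.uint16)
        ds.Rows, ds.Columns = frame.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{1.0 / scale:.10g}"
        ds.RescaleIntercept = f"{lo:.10g}"
        ds.PixelData = frame.tobytes()
        p = out_dir / f"frame_{i:03d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


def write_pd_frames(pd_frames, path) -> Path:
    """Write proton-density frames as a NIfTI volume (x, y, 1, n)."""
    import nibabel as nib

    arr = np.stack([np.asarray(f, float).T for f in pd_frames], axis=-1)[:, :, np.newaxis, :]
    nib.Nifti1Image(arr.astype(np.float32), np.eye(4)).to_filename(str(Path(path)))
    return Path(path)


def read_pd_frames(path) -> list[np.ndarray]:
    """Read proton-density frames written by :func:`write_pd_frames`."""
    import nibabel as nib

    arr = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if arr.ndim == 4:
        return [arr[:, :, 0, i].T for i in range(arr.shape[3])]
    if arr.ndim == 3:
        return [arr[:, :, i].T for i in range(arr.shape[2])]
    if arr.ndim == 2:
        return [arr.T]
    raise FormatError(f"unexpected PD volume dimensionality: {arr.ndim}")


def write_aif(curve, path) -> Path:
    """Write an AIF curve to CSV (columns ``time_s``, ``signal_au``).

    A JSON sidecar ``<stem>.json`` records the extraction threshold,
    percentile, selected pixel count and (if attached) timing points.
    """
    path = Path(path)
    if len(curve.times) == 0:
        raise ValueError("cannot write an empty AIF curve")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "signal_au"])
        for t, v in zip(curve.times, curve.values):
            w.writerow([f"{t:.6g}", f"{v:.10g}"])
    sidecar = {
        "percentile": curve.percentile,
        "threshold": curve.threshold,
        "n_pixels": int(curve.pixel_mask.sum()) if curve.pixel_mask is not None else None,
    }
    if curve.timing is not None:
        sidecar["timing_points"] = {
            "baseline_time_s": curve.timing.baseline_time,
            "start_time_s": curve.timing.start_time,
            "peak_time_s": curve.timing.peak_time,
        }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_aif(path):
    """Read an AIF curve written by :func:`write_aif`."""
    from .aif import AIFCurve

    path = Path(path)
    times, values = [], []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[:2] != ["time_s", "signal_au"]:
            raise FormatError(f"unexpected AIF CSV header: {header}")
        for row in r:
            times.append(float(row[0]))
            values.append(float(row[1]))
    percentile = None
    threshold = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        percentile = meta.get("percentile")
        threshold = meta.get("threshold")
    return AIFCurve(
        times=np.asarray(times), values=np.asarray(values),
        pixel_mask=None, percentile=percentile, threshold=threshold,
    )
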