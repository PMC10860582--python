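"""Reading and writing the pipeline's on-disk formats.

Image volumes travel as NIfTI-1 (spacing in mm in the affine); dynamic CTP
series carry their frame times in a JSON sidecar next to the image file.
Curves are CSV with columns ``time_s, hu, label``; ROI specs are JSON
(center in mm + radius in mm) or NIfTI label masks; cohorts are CSV with
one row per patient using the :class:`~ctaphase.pipeline.PatientRecord`
field names as columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .pipeline import frame_to_records, records_to_frame
from .tac import CtaVolume, CtpSeries, RoiSpec, TimeAttenuationCurve

__all__ = [
    "save_ctp_series",
    "load_ctp_series",
    "save_volume",
    "load_volume",
    "save_curve",
    "load_curve",
    "load_roi",
    "save_cohort_csv",
    "load_cohort_csv",
]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_ctp_series(series: CtpSeries, path) -> Path:
    """Write a 4D CTP series as NIfTI plus a frame-time JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.voxels, _affine(series.spacing)), str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"frame_times_s": series.frame_times.tolist()}))
    return path


def load_ctp_series(path, sidecar=None) -> CtpSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = json.loads(sidecar.read_text())
    return CtpSeries(data, np.asarray(meta["frame_times_s"], dtype=float), spacing)


def save_volume(volume, path) -> Path:
    """Write a 3D volume (CtaVolume or bare ndarray + spacing tuple)."""
    path = Path(path)
    if isinstance(volume, CtaVolume):
        data, spacing = volume.voxels, volume.spacing
    else:
        data, spacing = volume
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=float), _affine(spacing)), str(path))
    return path


def load_volume(path) -> CtaVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CtaVolume(data, spacing)


def save_curve(curve: TimeAttenuationCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": curve.times, "hu": curve.values, "label": curve.label}
    ).to_csv(path, index=False)
    return path


def load_curve(path) -> TimeAttenuationCurve:
    df = pd.read_csv(path)
    label = str(df["label"].iloc[0]) if "label" in df and len(df) else "AIF"
    return TimeAttenuationCurve(df["time_s"].to_numpy(), df["hu"].to_numpy(), label)


def load_roi(path, label: str | None = None) -> RoiSpec:
    """Load an ROI from a JSON sphere spec or a NIfTI mask.

    JSON schema: ``{"label": "arterial", "center_mm": [x, y, z],
    "radius_mm": r}``.
    """
    path = Path(path)
    if path.suffix == ".json":
        spec = json.loads(path.read_text())
        return RoiSpec(
            label=spec.get("label", label or "arterial"),
            center_mm=tuple(spec["center_mm"]),
            radius_mm=float(spec["radius_mm"]),
        )
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    return RoiSpec(label=label or "arterial", mask=mask)


def save_cohort_csv(records, path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def load_cohort_csv(path) -> list:
    return frame_to_records(pd.read_csv(path))
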