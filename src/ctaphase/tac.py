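"""Time-attenuation curve extraction from dynamic CTP and single-phase CTA.

A CT-perfusion (CTP) study is a 4D series of head volumes acquired every
couple of seconds while an iodinated contrast bolus passes through the
cerebral circulation.  The attenuation (in Hounsfield units, HU) of an
arterial region of interest traces the arterial input function (AIF); a
venous ROI — conventionally in the superior sagittal sinus — traces the
venous output function (VOF).  A single-phase CT angiogram (CTA) freezes the
same dynamics at one unknown time point, so its ROI values are constants.

This module provides the containers for both modalities, ROI definitions,
mean-HU curve extraction, a whole-field-of-view mean curve (a surrogate for
overall brain attenuation), and a translation-only motion correction that
re-aligns each CTP frame to the first one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CtpSeries",
    "CtaVolume",
    "RoiSpec",
    "TimeAttenuationCurve",
    "MotionCorrectionResult",
    "motion_correct",
    "extract_roi_curve",
    "fov_mean_curve",
    "cta_roi_values",
]


def _validate_spacing(spacing) -> tuple:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclass
class CtpSeries:
    """4D dynamic CT-perfusion series.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz, nt)
        Attenuation in HU.
    frame_times : ndarray, shape (nt,)
        Acquisition time of each frame in seconds, strictly increasing.
    spacing : tuple of float
        Voxel spacing in mm per spatial axis.
    """

    voxels: np.ndarray
    frame_times: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("CtpSeries voxels must be 4D (x, y, z, t)")
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.voxels.shape[3]:
            raise ValueError("frame_times length must equal the number of timesteps")
        if len(self.frame_times) >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def grid_shape(self) -> tuple:
        return self.voxels.shape[:3]

    def frame(self, i: int) -> np.ndarray:
        return self.voxels[..., i]


@dataclass
class CtaVolume:
    """Single-phase CTA volume: one 3D snapshot of the passing bolus.

    ``t_acq`` is the ground-truth acquisition time when the volume comes from
    the synthetic generator; it is ``None`` for real data, where recovering it
    is the whole point of the timing analysis.
    """

    voxels: np.ndarray
    spacing: tuple
    t_acq: float | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("CtaVolume voxels must be 3D")
        self.spacing = _validate_spacing(self.spacing)


@dataclass
class RoiSpec:
    """A region of interest, given either as a boolean mask or a sphere.

    ``label`` is ``"arterial"`` or ``"venous"``. A sphere is defined by its
    center and radius in mm (scanner/world units along each voxel axis).
    """

    label: str
    mask: np.ndarray | None = None
    center_mm: tuple | None = None
    radius_mm: float | None = None

    def __post_init__(self):
        if self.label not in ("arterial", "venous"):
            raise ValueError(f"ROI label must be 'arterial' or 'venous', got {self.label!r}")
        if self.mask is None and (self.center_mm is None or self.radius_mm is None):
            raise ValueError("RoiSpec needs either a mask or center_mm + radius_mm")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def resolve(self, grid_shape: tuple, spacing: tuple) -> np.ndarray:
        """Return the boolean voxel mask of this ROI on the given grid."""
        if self.mask is not None:
            if self.mask.shape != tuple(grid_shape):
                raise ValueError(
                    f"ROI mask shape {self.mask.shape} does not match grid {tuple(grid_shape)}"
                )
            mask = self.mask
        else:
            if self.radius_mm <= 0:
                raise ValueError("ROI radius must be positive")
            grids = np.meshgrid(
                *(np.arange(n) * s for n, s in zip(grid_shape, spacing)), indexing="ij"
            )
            d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center_mm))
            mask = d2 <= self.radius_mm**2
        if not mask.any():
            raise ValueError(f"ROI '{self.label}' is empty on this grid")
        return mask


@dataclass
class TimeAttenuationCurve:
    """Sampled HU values over acquisition time for one labelled source."""

    times: np.ndarray
    values: np.ndarray
    label: str  # AIF | VOF | FOV_mean | AIF_minus_VOF

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("curve times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def value_at(self, t) -> np.ndarray:
        """Piecewise-linear interpolation of the curve at time(s) ``t``."""
        return np.interp(t, self.times, self.values)


@dataclass
class MotionCorrectionResult:
    series: CtpSeries
    shifts_vox: np.ndarray  # (nt, 3) integer voxel shifts applied to each frame
    shifts_mm: np.ndarray  # (nt, 3) same shifts in mm
    flags: list = field(default_factory=list)


def _best_circular_shift(ref: np.ndarray, frame: np.ndarray, radius: int) -> tuple:
    """Integer shift (dx, dy, dz) maximizing correlation of roll(frame) with ref.

    Uses FFT circular cross-correlation; because a circular shift preserves the
    frame's mean and variance, the plain correlation argmax equals the
    normalized cross-correlation argmax.  Scores within a relative 1e-9 of
    the maximum are treated as tied (FFT round-off on a structureless
    landscape must not invent motion) and resolve toward the smallest shift
    magnitude, then lexicographically.
    """
    axes = (0, 1, 2)
    c = np.fft.irfftn(np.fft.rfftn(ref, axes=axes) * np.conj(np.fft.rfftn(frame, axes=axes)),
                      s=ref.shape, axes=axes)
    r = range(-radius, radius + 1)
    n = ref.shape
    scored = [
        (c[dx % n[0], dy % n[1], dz % n[2]], (dx, dy, dz))
        for dx in r for dy in r for dz in r
    ]
    cmax = max(s for s, _ in scored)
    tol = 1e-9 * max(abs(cmax), 1.0)
    tied = [d for s, d in scored if s >= cmax - tol]
    return min(tied, key=lambda d: (abs(d[0]) + abs(d[1]) + abs(d[2]), d))


def motion_correct(series: CtpSeries, search_radius: int = 3) -> MotionCorrectionResult:
    """Translation-only motion correction of a CTP series.

    Every frame after the first is shifted by the integer-voxel translation
    that maximizes its normalized cross-correlation with frame 0, searched
    within ``search_radius`` voxels per axis.  Frame 0 is never touched.
    Degenerate (constant) frames carry no alignment information and are left
    in place with a warning flag.
    """
    if series.n_frames < 2:
        raise ValueError("motion correction needs at least 2 frames")
    if search_radius < 0:
        raise ValueError("search_radius must be non-negative")
    ref = series.frame(0)
    out = np.empty_like(series.voxels)
    out[..., 0] = ref
    shifts = np.zeros((series.n_frames, 3), dtype=int)
    flags: list = []
    for i in range(1, series.n_frames):
        frm = series.frame(i)
        if np.ptp(frm) == 0:
            flags.append(f"frame {i}: constant frame, no correction applied")
            out[..., i] = frm
            continue
        shift = _best_circular_shift(ref, frm, search_radius) if search_radius else (0, 0, 0)
        shifts[i] = shift
        out[..., i] = np.roll(frm, shift, axis=(0, 1, 2))
    corrected = CtpSeries(out, series.frame_times.copy(), series.spacing)
    shifts_mm = shifts * np.asarray(series.spacing)
    return MotionCorrectionResult(corrected, shifts, shifts_mm, flags)


def extract_roi_curve(series: CtpSeries, roi: RoiSpec) -> TimeAttenuationCurve:
    """Mean-HU time-attenuation curve over an ROI of a CTP series."""
    mask = roi.resolve(series.grid_shape, series.spacing)
    values = series.voxels[mask].mean(axis=0)
    label = "AIF" if roi.label == "arterial" else "VOF"
    return TimeAttenuationCurve(series.frame_times.copy(), values, label)


def fov_mean_curve(
    series: CtpSeries, brain_mask: np.ndarray | None = None
) -> TimeAttenuationCurve:
    """Per-frame mean HU over the whole field of view (or a brain mask).

    Used as a surrogate for overall brain attenuation during bolus passage.
    """
    if brain_mask is None:
        values = series.voxels.reshape(-1, series.n_frames).mean(axis=0)
    else:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != series.grid_shape:
            raise ValueError("brain_mask shape must match the series grid")
        if not brain_mask.any():
            raise ValueError("brain_mask is empty")
        values = series.voxels[brain_mask].mean(axis=0)
    return TimeAttenuationCurve(series.frame_times.copy(), values, "FOV_mean")


def cta_roi_values(cta: CtaVolume, arterial: RoiSpec, venous: RoiSpec) -> tuple:
    """Mean HU of the arterial and venous ROIs on a single-phase CTA.

    Returns ``(arterial_hu, venous_hu)``. The two ROIs must not overlap —
    artery and draining vein are distinct structures.
    """
    a_mask = arterial.resolve(cta.voxels.shape, cta.spacing)
    v_mask = venous.resolve(cta.voxels.shape, cta.spacing)
    if np.any(a_mask & v_mask):
        raise ValueError("arterial and venous ROIs overlap")
    return float(cta.voxels[a_mask].mean()), float(cta.voxels[v_mask].mean())
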