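"""Perfusion volumetry: core/penumbra volumes, HIR, and lesion filtering.

Operational definitions follow standard automated perfusion software for
acute ischaemic stroke: the infarct core is tissue with relative cerebral
blood flow below 30% of normal, the ischaemic penumbra is tissue with
time-to-maximum (Tmax) above 6 s, and the hypoperfusion intensity ratio
(HIR) is the volume with Tmax > 10 s divided by the volume with
Tmax > 6 s — a surrogate for collateral quality (lower is better).

Lesion probability maps are binarized at probability >= 0.5; connected
components with volume <= 0.1 mL are discarded, as are components lying
(by majority voxel) in the contralateral hemisphere or cerebellum, since in
large-vessel-occlusion stroke the affected hemisphere is known from the CTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "IPSILATERAL",
    "CONTRALATERAL",
    "CEREBELLUM",
    "OUTSIDE",
    "PerfusionMaps",
    "ProbabilityMap",
    "VolumeResult",
    "voxel_volume_mL",
    "thresholded_volume",
    "compute_hir",
    "classify_collaterals_hir",
    "lesion_volume_from_probability",
]

# Hemisphere label codes
OUTSIDE = 0
IPSILATERAL = 1
CONTRALATERAL = 2
CEREBELLUM = 3


def voxel_volume_mL(spacing) -> float:
    """Volume of one voxel in mL (= mm^3 / 1000)."""
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing[0] * spacing[1] * spacing[2] / 1000.0


@dataclass
class PerfusionMaps:
    """rCBF-ratio (relative to contralateral, dimensionless) and Tmax (s) maps."""

    rcbf_ratio: np.ndarray
    tmax: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.rcbf_ratio = np.asarray(self.rcbf_ratio, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if self.rcbf_ratio.shape != self.tmax.shape or self.rcbf_ratio.ndim != 3:
            raise ValueError("rcbf_ratio and tmax must be 3D maps of identical shape")
        if np.any(self.rcbf_ratio < 0) or np.any(self.tmax < 0):
            raise ValueError("rCBF ratio and Tmax must be non-negative")
        voxel_volume_mL(self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)

    def core_volume_mL(self, rcbf_threshold: float = 0.3) -> float:
        """Infarct core volume: rCBF ratio < threshold (default 30%)."""
        return thresholded_volume(self.rcbf_ratio, lambda m: m < rcbf_threshold, self.spacing)

    def penumbra_volume_mL(self, tmax_threshold: float = 6.0) -> float:
        """Hypoperfused volume: Tmax > threshold (default 6 s)."""
        return thresholded_volume(self.tmax, lambda m: m > tmax_threshold, self.spacing)


@dataclass
class ProbabilityMap:
    """Voxelwise lesion probability map with hemisphere labels."""

    values: np.ndarray
    spacing: tuple
    hemisphere_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("probability map must be 3D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.hemisphere_mask is None:
            raise ValueError("hemisphere labels are required for lesion filtering")
        self.hemisphere_mask = np.asarray(self.hemisphere_mask)
        if self.hemisphere_mask.shape != self.values.shape:
            raise ValueError("hemisphere_mask shape must match the probability map")
        voxel_volume_mL(self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class VolumeResult:
    volume_mL: float
    n_components_kept: int
    n_components_rejected: int


def thresholded_volume(map_3d: np.ndarray, predicate, spacing) -> float:
    """Volume (mL) of the voxels satisfying ``predicate``.

    ``predicate`` is either a callable mapping the array to a boolean mask
    (e.g. ``lambda m: m > 6``) or a precomputed boolean mask.
    """
    map_3d = np.asarray(map_3d, dtype=float)
    if not np.all(np.isfinite(map_3d)):
        raise ValueError("map contains non-finite values")
    mask = predicate(map_3d) if callable(predicate) else np.asarray(predicate, dtype=bool)
    if mask.shape != map_3d.shape:
        raise ValueError("predicate mask shape mismatch")
    return int(mask.sum()) * voxel_volume_mL(spacing)


def compute_hir(maps: PerfusionMaps, severe_s: float = 10.0, any_s: float = 6.0) -> float:
    """Hypoperfusion intensity ratio: volume(Tmax>10 s) / volume(Tmax>6 s).

    Because the Tmax>10 s region is nested inside the Tmax>6 s region, the
    ratio always lies in [0, 1].  Raises if no voxel exceeds the 6 s
    threshold (the ratio is then undefined; the caller decides handling).
    """
    if severe_s < any_s:
        raise ValueError("severe threshold must be >= the any-delay threshold")
    denom = thresholded_volume(maps.tmax, lambda m: m > any_s, maps.spacing)
    if denom == 0:
        raise ZeroDivisionError("HIR undefined: no voxel with Tmax above the 6 s threshold")
    num = thresholded_volume(maps.tmax, lambda m: m > severe_s, maps.spacing)
    return num / denom


def classify_collaterals_hir(hir: float) -> str:
    """Dichotomize HIR into collateral status: < 0.5 good, >= 0.5 poor."""
    if not (0.0 <= hir <= 1.0):
        raise ValueError(f"HIR must be in [0, 1], got {hir}")
    return "good" if hir < 0.5 else "poor"


# Majority-vote precedence when a component straddles label boundaries with
# an exact tie: keep it (ipsilateral wins), then contralateral, cerebellum.
_LABEL_PRECEDENCE = (IPSILATERAL, CONTRALATERAL, CEREBELLUM, OUTSIDE)


def lesion_volume_from_probability(
    pmap: ProbabilityMap,
    prob_threshold: float = 0.5,
    min_volume_mL: float = 0.1,
    connectivity: int = 26,
) -> VolumeResult:
    """Filtered lesion volume from a probability map.

    Binarize at probability >= ``prob_threshold``; label 3D connected
    components (26-connectivity by default); reject components whose volume
    is <= ``min_volume_mL`` (strict ``>`` rule for inclusion) or whose
    majority voxel lies in the contralateral hemisphere or cerebellum.
    Returns the summed volume of kept components and the kept/rejected
    counts.
    """
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    binary = pmap.values >= prob_threshold
    labels, n_comp = ndimage.label(binary, structure=structure)
    vv = voxel_volume_mL(pmap.spacing)
    kept = rejected = 0
    total = 0.0
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        vol = int(comp_mask.sum()) * vv
        if vol <= min_volume_mL:
            rejected += 1
            continue
        region_labels = pmap.hemisphere_mask[comp_mask]
        counts = {lab: int(np.sum(region_labels == lab)) for lab in _LABEL_PRECEDENCE}
        majority = max(_LABEL_PRECEDENCE, key=lambda lab: (counts[lab], -_LABEL_PRECEDENCE.index(lab)))
        if majority in (CONTRALATERAL, CEREBELLUM):
            rejected += 1
            continue
        kept += 1
        total += vol
    return VolumeResult(volume_mL=total, n_components_kept=kept, n_components_rejected=rejected)
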