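"""Synthetic contrast-bolus phantoms, perfusion maps and stroke cohorts.

Everything downstream of this module (curve extraction, timing estimation,
volumetry, stratified agreement statistics) can run on data generated here
with known ground truth, so the whole pipeline is testable without any
patient imaging.

The first-pass bolus is modelled as a gamma-variate

    C(t) = A * ((t - t0) / (alpha*beta))**alpha * exp(alpha - (t - t0)/beta)

for t > t0 and 0 otherwise, normalized so that the peak value is exactly
``A`` at t = t0 + alpha*beta.  The venous output function is the arterial
curve delayed by the venous onset lag and convolved with an exponential
transit-time kernel (area preserved): venous enhancement begins a few
seconds after arterial onset, while most of the peak-to-peak lag and the
flatter, right-skewed venous shape come from capillary-bed dispersion —
the behaviour seen in superior-sagittal-sinus curves.  Tissue is a
low-amplitude scaled copy of the arterial curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tac import CtaVolume, CtpSeries, RoiSpec, TimeAttenuationCurve
from .volumetry import (
    CEREBELLUM,
    CONTRALATERAL,
    IPSILATERAL,
    PerfusionMaps,
    ProbabilityMap,
)
from .pipeline import PatientRecord

__all__ = [
    "BolusParams",
    "BolusModel",
    "PhantomGeometry",
    "PhantomTruth",
    "CohortParams",
    "gamma_variate",
    "simulate_ctp_series",
    "simulate_cta_snapshot",
    "simulate_perfusion_maps",
    "simulate_probability_map",
    "simulate_cohort",
    "preset_test_bolus_t_acq",
]


@dataclass(frozen=True)
class BolusParams:
    """Parameters of the synthetic first-pass contrast bolus.

    Defaults describe a typical fast cerebral CTP acquisition: bolus arrival
    ~12 s after scan start, arterial peak enhancement 180 HU over a 40 HU
    brain baseline, venous onset lag 3.5 s with a ~4 s dispersion time
    constant (peak-to-peak arteriovenous lag ~7 s), and 40 frames at 2 s.

    Attributes
    ----------
    t0 : bolus arrival time (s)
    alpha, beta : gamma-variate shape (–) and scale (s); the arterial peak
        occurs at ``t0 + alpha*beta``
    amplitude : peak arterial enhancement above baseline (HU)
    baseline : pre-contrast attenuation (HU)
    venous_delay : AIF-to-VOF onset lag (s)
    venous_dispersion : venous broadening factor (–, >=1); the exponential
        transit-kernel time constant is ``(venous_dispersion - 1)`` times
        the bolus SD ``sqrt(alpha)*beta``, so 1 means no broadening
    noise_sd : additive Gaussian noise per voxel-frame (HU)
    frame_interval : CTP sampling period (s)
    n_frames : number of timesteps
    seed : RNG seed for the noise
    tissue_fraction : tissue enhancement as a fraction of the arterial curve
    """

    t0: float = 12.0
    alpha: float = 3.0
    beta: float = 1.5
    amplitude: float = 180.0
    baseline: float = 40.0
    venous_delay: float = 3.5
    venous_dispersion: float = 2.5
    noise_sd: float = 5.0
    frame_interval: float = 2.0
    n_frames: int = 40
    seed: int = 0
    tissue_fraction: float = 0.05

    def __post_init__(self):
        numeric = [
            self.t0, self.alpha, self.beta, self.amplitude, self.baseline,
            self.venous_delay, self.venous_dispersion, self.noise_sd,
            self.frame_interval, self.tissue_fraction,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("all bolus parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.venous_delay < 0:
            raise ValueError("venous_delay must be non-negative")
        if self.venous_dispersion < 1:
            raise ValueError("venous_dispersion must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


def gamma_variate(t, params: BolusParams):
    """Gamma-variate enhancement (HU above baseline) at time(s) ``t``.

    Zero for t <= t0; peak value equals ``params.amplitude`` exactly at
    t = t0 + alpha*beta by construction.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    tau = t - params.t0
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / (params.alpha * params.beta)
    out[pos] = params.amplitude * x**params.alpha * np.exp(params.alpha - tau[pos] / params.beta)
    return float(out) if out.ndim == 0 else out


class BolusModel:
    """Continuous-time AIF / VOF / tissue curves for a parameter set.

    The VOF is computed once on a fine internal grid (20 Hz) by convolving
    the onset-delayed arterial curve with a normalized exponential
    transit-time kernel, and interpolated on query.  Convolution with a
    unit-area kernel preserves the bolus area up to grid truncation; the
    exponential kernel skews the venous curve right, so its peak lags the
    arterial peak by the onset delay plus a dispersion-dependent shift.
    """

    _DT = 0.05

    def __init__(self, params: BolusParams):
        self.params = params
        tau = self.transit_tau(params)
        margin = params.venous_delay + 10.0 * tau + 20.0
        self._tg = np.arange(0.0, params.duration + margin, self._DT)
        aif_shifted = gamma_variate(self._tg - params.venous_delay, params)
        if tau > 1e-9:
            n_k = int(np.ceil(12 * tau / self._DT)) + 1
            k = np.exp(-(np.arange(n_k) * self._DT) / tau)
            k /= k.sum()
            self._vof = np.convolve(aif_shifted, k)[: len(self._tg)]
        else:
            self._vof = aif_shifted

    @staticmethod
    def transit_tau(params: BolusParams) -> float:
        """Time constant (s) of the exponential venous transit kernel."""
        return (params.venous_dispersion - 1.0) * math.sqrt(params.alpha) * params.beta

    def aif(self, t):
        """Arterial enhancement (HU above baseline)."""
        return gamma_variate(t, self.params)

    def vof(self, t):
        """Venous enhancement (HU above baseline)."""
        if self.transit_tau(self.params) <= 1e-9:
            # no dispersion: the delayed arterial curve, evaluated exactly
            return gamma_variate(np.asarray(t, float) - self.params.venous_delay, self.params)
        return np.interp(t, self._tg, self._vof)

    def tissue(self, t):
        """Background tissue enhancement (HU above baseline)."""
        return self.params.tissue_fraction * self.aif(t)

    @property
    def aif_peak_time(self) -> float:
        return self.params.t0 + self.params.alpha * self.params.beta

    @property
    def vof_peak_time(self) -> float:
        return float(self._tg[int(np.argmax(self._vof))])

    def washout_end(self, frac: float = 0.15) -> float:
        """Last time the venous enhancement is >= ``frac`` of its peak,
        capped at the end of the sampled acquisition window."""
        peak = self._vof.max()
        above = np.nonzero(self._vof >= frac * peak)[0]
        t_end = float(self._tg[above[-1]]) if len(above) else self.params.duration
        return min(t_end, self.params.duration)

    def bolus_window(self) -> tuple:
        """(start, end) of the informative bolus passage on the CTP axis."""
        return (self.params.t0 + 0.5, self.washout_end())


@dataclass(frozen=True)
class PhantomGeometry:
    """Digital phantom layout: grid, spacing, vessel ROIs, and a skull shell.

    ROI radii are in voxel units; the defaults give ~33-voxel ROIs on a
    24 x 24 x 12 grid with 1 x 1 x 2 mm spacing.  A static high-attenuation
    shell on the grid borders stands in for the skull (including base and
    vertex): it carries no contrast dynamics but anchors intensity-based
    motion correction on every axis, exactly as bone does on real head CT.
    """

    shape: tuple = (24, 24, 12)
    spacing: tuple = (1.0, 1.0, 2.0)
    arterial_center: tuple = (6.0, 6.0, 6.0)
    arterial_radius: float = 2.0
    venous_center: tuple = (17.0, 17.0, 6.0)
    venous_radius: float = 2.0
    skull_thickness: int = 1  # border voxels on every axis; 0 disables the shell
    skull_hu: float = 900.0

    def _sphere(self, center, radius) -> np.ndarray:
        grids = np.meshgrid(*(np.arange(n, dtype=float) for n in self.shape), indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return d2 <= radius**2

    def arterial_mask(self) -> np.ndarray:
        return self._sphere(self.arterial_center, self.arterial_radius)

    def venous_mask(self) -> np.ndarray:
        return self._sphere(self.venous_center, self.venous_radius)

    def skull_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        t = self.skull_thickness
        if t > 0:
            mask[:t, :, :] = mask[-t:, :, :] = True
            mask[:, :t, :] = mask[:, -t:, :] = True
            mask[:, :, :t] = mask[:, :, -t:] = True  # skull base and vertex
        return mask

    def validate(self):
        a, v, s = self.arterial_mask(), self.venous_mask(), self.skull_mask()
        if not a.any() or not v.any():
            raise ValueError("phantom ROI is empty")
        if np.any(a & v):
            raise ValueError("phantom arterial and venous ROIs overlap")
        if np.any((a | v) & s):
            raise ValueError("phantom vessel ROI touches the skull shell")

    def arterial_roi(self) -> RoiSpec:
        return RoiSpec("arterial", mask=self.arterial_mask())

    def venous_roi(self) -> RoiSpec:
        return RoiSpec("venous", mask=self.venous_mask())


@dataclass
class PhantomTruth:
    """Noiseless ground truth accompanying a simulated series/snapshot."""

    model: BolusModel
    geometry: PhantomGeometry
    aif: TimeAttenuationCurve
    vof: TimeAttenuationCurve
    fov_mean: TimeAttenuationCurve


def _truth_curves(model: BolusModel, geometry: PhantomGeometry) -> PhantomTruth:
    p = model.params
    times = p.frame_times
    aif = p.baseline + model.aif(times)
    vof = p.baseline + model.vof(times)
    a_mask, v_mask = geometry.arterial_mask(), geometry.venous_mask()
    s_mask = geometry.skull_mask()
    n_total = int(np.prod(geometry.shape))
    n_a, n_v, n_s = int(a_mask.sum()), int(v_mask.sum()), int(s_mask.sum())
    tis = p.baseline + model.tissue(times)
    fov = (
        n_a * aif + n_v * vof + n_s * geometry.skull_hu + (n_total - n_a - n_v - n_s) * tis
    ) / n_total
    return PhantomTruth(
        model,
        geometry,
        TimeAttenuationCurve(times, aif, "AIF"),
        TimeAttenuationCurve(times, vof, "VOF"),
        TimeAttenuationCurve(times, fov, "FOV_mean"),
    )


def simulate_ctp_series(
    bolus: BolusParams, geometry: PhantomGeometry | None = None
) -> tuple[CtpSeries, PhantomTruth]:
    """Simulate a dynamic CTP series plus its noiseless ground truth.

    Arterial voxels follow baseline + AIF, venous voxels the delayed and
    broadened venous curve, everything else a low-amplitude tissue curve.
    Gaussian noise of ``bolus.noise_sd`` HU is added per voxel-frame from
    ``bolus.seed``, so identical parameters give bit-identical output.
    """
    geometry = geometry or PhantomGeometry()
    geometry.validate()
    model = BolusModel(bolus)
    truth = _truth_curves(model, geometry)
    p = bolus
    times = p.frame_times
    data = np.empty(geometry.shape + (p.n_frames,), dtype=float)
    tis = p.baseline + model.tissue(times)
    data[...] = tis  # broadcast over the trailing time axis
    data[geometry.arterial_mask()] = truth.aif.values
    data[geometry.venous_mask()] = truth.vof.values
    data[geometry.skull_mask()] = geometry.skull_hu
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        data = data + rng.normal(0.0, p.noise_sd, size=data.shape)
    return CtpSeries(data, times, geometry.spacing), truth


def simulate_cta_snapshot(
    bolus: BolusParams, geometry: PhantomGeometry | None = None, t_acq: float = 0.0
) -> CtaVolume:
    """Single-time-point CTA snapshot of the same bolus dynamics at ``t_acq``.

    Intensities are the dynamic curves evaluated at ``t_acq`` plus noise;
    the ground-truth acquisition time is recorded on the returned volume.
    """
    geometry = geometry or PhantomGeometry()
    geometry.validate()
    if not (0.0 <= t_acq <= bolus.duration):
        raise ValueError(
            f"t_acq={t_acq} outside the simulated window [0, {bolus.duration}]"
        )
    model = BolusModel(bolus)
    p = bolus
    data = np.full(geometry.shape, p.baseline + model.tissue(t_acq), dtype=float)
    data[geometry.arterial_mask()] = p.baseline + model.aif(t_acq)
    data[geometry.venous_mask()] = p.baseline + model.vof(t_acq)
    data[geometry.skull_mask()] = geometry.skull_hu
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        data = data + rng.normal(0.0, p.noise_sd, size=data.shape)
    return CtaVolume(data, geometry.spacing, t_acq=float(t_acq))


def preset_test_bolus_t_acq(
    bolus: BolusParams,
    test_bolus_lead: float = 10.0,
    post_peak_delay: float = 12.0,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Acquisition time under a "test-bolus peak + 12 s" CTA protocol.

    The timing test bolus is a short injection whose ascending-aorta peak
    precedes the cerebral arterial peak of the main bolus: the aorta enhances
    a few seconds earlier and the shorter injection peaks sooner.  That lead
    is modelled as a single parameter (default 10 s), so

        t_acq = (aif_peak_time - test_bolus_lead) + post_peak_delay

    which with the defaults places the scan ~2 s after the cerebral arterial
    peak — in the mid-arterial phase.  Optional Gaussian jitter emulates
    scan-trigger variability; the result is clipped to the acquisition window.
    """
    peak = bolus.t0 + bolus.alpha * bolus.beta
    t_acq = peak - test_bolus_lead + post_peak_delay
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(bolus.seed)
        t_acq += rng.normal(0.0, jitter_sd)
    return float(np.clip(t_acq, 0.0, bolus.duration))


# ---------------------------------------------------------------------------
# Perfusion and probability maps
# ---------------------------------------------------------------------------


def _ordered_lesion_voxels(shape: tuple, center: tuple) -> np.ndarray:
    """Flat voxel indices sorted by distance from ``center`` (lexicographic
    tie-break), so taking the first k voxels grows a deterministic blob."""
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center)).ravel()
    return np.argsort(d2, kind="stable")


def simulate_perfusion_maps(
    core_volume_mL: float,
    penumbra_volume_mL: float,
    hir_target: float,
    geometry: PhantomGeometry | None = None,
    seed: int = 0,
) -> PerfusionMaps:
    """Simulate rCBF-ratio and Tmax maps with prescribed thresholded volumes.

    The hypoperfused lesion (Tmax > 6 s) is a blob grown from the grid centre
    with exactly ``round(penumbra_volume_mL / voxel_volume)`` voxels; a
    nested ``hir_target`` fraction of those voxels gets Tmax > 10 s, and the
    innermost core voxels get rCBF ratio < 0.3.  Voxel values inside each
    compartment are jittered (seeded) but never cross the thresholds, so
    thresholded volumes are exact by construction.
    """
    geometry = geometry or PhantomGeometry()
    if core_volume_mL < 0 or penumbra_volume_mL < 0:
        raise ValueError("volumes must be non-negative")
    if core_volume_mL > penumbra_volume_mL:
        raise ValueError("core volume must not exceed penumbra volume")
    if not (0.0 <= hir_target <= 1.0):
        raise ValueError("hir_target must be in [0, 1]")
    voxel_mL = float(np.prod(geometry.spacing)) / 1000.0
    n_total = int(np.prod(geometry.shape))
    n_pen = int(round(penumbra_volume_mL / voxel_mL))
    n_core = int(round(core_volume_mL / voxel_mL))
    n_t10 = int(round(hir_target * n_pen))
    if n_pen > n_total:
        raise ValueError(
            f"requested penumbra ({n_pen} voxels) exceeds grid capacity ({n_total})"
        )
    rng = np.random.default_rng(seed)
    center = tuple((n - 1) / 2.0 for n in geometry.shape)
    order = _ordered_lesion_voxels(geometry.shape, center)

    tmax = rng.uniform(0.5, 3.0, size=n_total)
    tmax[order[:n_pen]] = rng.uniform(6.5, 9.5, size=n_pen)
    tmax[order[:n_t10]] = rng.uniform(10.5, 14.0, size=n_t10)
    rcbf = rng.uniform(0.8, 1.2, size=n_total)
    rcbf[order[:n_core]] = rng.uniform(0.05, 0.25, size=n_core)
    return PerfusionMaps(
        rcbf_ratio=rcbf.reshape(geometry.shape),
        tmax=tmax.reshape(geometry.shape),
        spacing=geometry.spacing,
    )


def default_hemisphere_labels(shape: tuple, cerebellum_slices: int = 2) -> np.ndarray:
    """Label map splitting the grid into ipsilateral (low x) and contralateral
    (high x) hemispheres, with the lowest ``cerebellum_slices`` z-slices as
    cerebellum."""
    labels = np.full(shape, CONTRALATERAL, dtype=np.int8)
    labels[: shape[0] // 2] = IPSILATERAL
    if cerebellum_slices > 0:
        labels[:, :, :cerebellum_slices] = CEREBELLUM
    return labels


def simulate_probability_map(
    lesions: list,
    geometry: PhantomGeometry | None = None,
    background_p: float = 0.02,
    hemisphere_mask: np.ndarray | None = None,
) -> ProbabilityMap:
    """Build a lesion probability map from spherical lesion specs.

    Each lesion is a dict with keys ``center`` (voxel coords), ``radius``
    (voxels) and ``p`` (probability assigned inside the sphere). Lesions are
    painted in order; the hemisphere label map defaults to an ipsilateral /
    contralateral split with a cerebellar slab (see
    :func:`default_hemisphere_labels`).
    """
    geometry = geometry or PhantomGeometry()
    values = np.full(geometry.shape, background_p, dtype=float)
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in geometry.shape), indexing="ij")
    for spec in lesions:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, spec["center"]))
        values[d2 <= spec["radius"] ** 2] = spec["p"]
    if hemisphere_mask is None:
        hemisphere_mask = default_hemisphere_labels(geometry.shape)
    return ProbabilityMap(values=values, spacing=geometry.spacing, hemisphere_mask=hemisphere_mask)


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of the synthetic stroke cohort.

    The CTA-based lesion estimate lies between the perfusion core and
    penumbra: ``estimate = core + lambda_penumbra*(penumbra - core) + noise``
    (floored at 0).  Final infarct volume is the core plus a fraction of the
    at-risk tissue that depends on reperfusion success and collateral
    quality: with ``collateral_effect > 1`` poor collaterals convert more
    penumbra into infarct.  Defaults follow a 121-patient anterior-circulation
    thrombectomy cohort: ~81% successful reperfusion, LKW-to-imaging times
    with median ~240 min, and ~2.5% unknown LKW.
    """

    n_patients: int = 121
    lambda_penumbra: float = 0.5
    estimate_noise_sd: float = 10.0
    collateral_effect: float = 2.0
    reperfusion_rate: float = 0.81
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 <= self.lambda_penumbra <= 1.0):
            raise ValueError("lambda_penumbra must be in [0, 1]")
        if not (0.0 <= self.reperfusion_rate <= 1.0):
            raise ValueError("reperfusion_rate must be in [0, 1]")
        if self.estimate_noise_sd < 0:
            raise ValueError("estimate_noise_sd must be non-negative")
        if self.collateral_effect <= 0:
            raise ValueError("collateral_effect must be positive")


_FUTILE_GRADES = ("0", "1", "2a")
_SUCCESS_GRADES = ("2b", "2c", "3")


def _clock(minutes: float) -> str:
    m = int(round(minutes)) % 1440
    return f"{m // 60:02d}:{m % 60:02d}"


def simulate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a synthetic patient cohort with known generative structure.

    Per patient: a latent collateral quality c ~ U(0,1) drives the HIR
    (≈ 1 − c), the Miteff grade (terciles of c), lesion size (poor
    collaterals → larger core), and the fraction of at-risk tissue that
    infarcts. TICI success is Bernoulli(``reperfusion_rate``); successful
    reperfusion converts a baseline 25% of the at-risk tissue, futile 65%,
    each scaled by ``1 + (collateral_effect − 1)(1 − c)`` and clipped to 1.
    """
    rng = np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    for i in range(params.n_patients):
        c = rng.uniform()
        hir = float(np.clip(1.0 - c + rng.normal(0.0, 0.08), 0.0, 1.0))
        miteff = 1 if c < 1 / 3 else (2 if c < 2 / 3 else 3)
        core = float(np.exp(rng.normal(np.log(10.0), 0.9)) * (0.6 + 1.2 * (1.0 - c)))
        at_risk = float(np.exp(rng.normal(np.log(45.0), 0.7)))
        penumbra = core + at_risk
        success = bool(rng.random() < params.reperfusion_rate)
        tici = str(rng.choice(_SUCCESS_GRADES if success else _FUTILE_GRADES))
        noise = rng.normal(0.0, params.estimate_noise_sd) if params.estimate_noise_sd > 0 else 0.0
        estimate = max(0.0, core + params.lambda_penumbra * at_risk + noise)
        f_base = 0.25 if success else 0.65
        f = float(np.clip(f_base * (1.0 + (params.collateral_effect - 1.0) * (1.0 - c)), 0.0, 1.0))
        fiv = core + f * at_risk
        unknown_lkw = bool(rng.random() < 0.025)
        lkw = None if unknown_lkw else float(np.exp(rng.normal(np.log(240.0), 0.8)))
        if lkw is not None:
            lkw = min(lkw, 1440.0)
        wake_up = bool(rng.random() < 0.2)
        sleep_time = wake_time = None
        if wake_up:
            sleep_min = rng.normal(22 * 60, 45.0)
            wake_min = rng.normal(6.5 * 60, 45.0)
            sleep_time, wake_time = _clock(sleep_min), _clock(wake_min)
        records.append(
            PatientRecord(
                id=f"P{i:04d}",
                cnn_volume_mL=estimate,
                fiv_mL=fiv,
                core_mL=core,
                penumbra_mL=penumbra,
                hir=hir,
                miteff=miteff,
                tici=tici,
                lkw_to_cta_min=lkw,
                wake_up=wake_up,
                sleep_time=sleep_time,
                wake_time=wake_time,
            )
        )
    return records
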