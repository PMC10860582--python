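"""CTA acquisition-phase estimation from CTP time-attenuation curves.

A single-phase CTA freezes the contrast bolus at one unknown time.  The
arterial-minus-venous (AIF − VOF) difference curve from the dynamic CTP
study of the same patient is, however, a function of bolus time — so the
constant AIF − VOF difference measured on the CTA intersects that curve at
the acquisition time.  This module finds those intersections on the
piecewise-linear interpolant, disambiguates multiple crossings using the
raw arterial and venous HU values, and assigns one of four bolus phases:

    early_arterial < mid_arterial < mid_to_venous < delayed_venous

with landmark-based boundaries: mid_arterial starts at the AIF peak,
delayed_venous at the VOF peak, and the mid point between the two peaks
separates mid_arterial from mid_to_venous.  The early-arterial phase starts
at the AIF half-peak upslope time; earlier estimates are flagged pre-bolus.
All estimates live on the CTP bolus time axis — no clock synchronization
between the two acquisitions is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tac import TimeAttenuationCurve

__all__ = [
    "PHASES",
    "DifferenceCurve",
    "Landmarks",
    "PhaseEstimate",
    "EstimationError",
    "resample_to_common_grid",
    "difference_curve",
    "find_intersections",
    "estimate_timing",
    "classify_phase",
    "phase_rank",
]

PHASES = ("early_arterial", "mid_arterial", "mid_to_venous", "delayed_venous")


class EstimationError(RuntimeError):
    """Raised when the difference curve carries no timing information."""


def phase_rank(phase: str) -> int:
    """Ordinal position of a phase label (0 = early_arterial ... 3)."""
    return PHASES.index(phase)


@dataclass
class DifferenceCurve:
    """Pointwise AIF − VOF curve on a common time grid."""

    times: np.ndarray
    values: np.ndarray
    provenance: tuple = ("AIF", "VOF")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def value_at(self, t):
        return np.interp(t, self.times, self.values)


@dataclass
class Landmarks:
    """Curve landmarks used for phase classification (all in s)."""

    aif_peak_time: float
    vof_peak_time: float
    aif_half_rise_time: float


@dataclass
class PhaseEstimate:
    """Estimated CTA acquisition time with its categorical bolus phase."""

    t_est: float
    candidates: np.ndarray
    phase: str
    landmarks: Landmarks
    quality_flags: list = field(default_factory=list)


def resample_to_common_grid(
    a: TimeAttenuationCurve, b: TimeAttenuationCurve
) -> tuple[TimeAttenuationCurve, TimeAttenuationCurve]:
    """Resample two curves onto the union of their time samples restricted to
    the overlap of their ranges (piecewise-linear interpolation)."""
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if hi <= lo:
        raise ValueError("curves have no overlapping time range")
    grid = np.union1d(a.times, b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    return (
        TimeAttenuationCurve(grid, a.value_at(grid), a.label),
        TimeAttenuationCurve(grid, b.value_at(grid), b.label),
    )


def difference_curve(aif: TimeAttenuationCurve, vof: TimeAttenuationCurve) -> DifferenceCurve:
    """Pointwise AIF − VOF on an identical time grid.

    Curves on different grids must be passed through
    :func:`resample_to_common_grid` first.
    """
    if len(aif.times) != len(vof.times) or not np.array_equal(aif.times, vof.times):
        raise ValueError(
            "AIF and VOF are sampled on different time grids; "
            "use resample_to_common_grid first"
        )
    return DifferenceCurve(aif.times.copy(), aif.values - vof.values, (aif.label, vof.label))


def find_intersections(curve: DifferenceCurve, level: float) -> np.ndarray:
    """All times where the piecewise-linear curve crosses a constant level.

    Crossings inside a bracketing segment are solved exactly; samples exactly
    equal to the level count once, at the sample time.  A level outside the
    curve's range yields an empty array (the caller flags it).
    """
    if len(curve.times) < 2:
        raise ValueError("difference curve needs at least 2 samples")
    t, y = curve.times, curve.values - float(level)
    roots = [t[i] for i in range(len(t)) if y[i] == 0.0]
    for i in range(len(t) - 1):
        if y[i] * y[i + 1] < 0:
            roots.append(t[i] - y[i] * (t[i + 1] - t[i]) / (y[i + 1] - y[i]))
    roots = np.sort(np.asarray(roots, dtype=float))
    if len(roots) > 1:  # drop duplicates from adjacent exact-zero samples
        keep = np.concatenate([[True], np.diff(roots) > 1e-12])
        roots = roots[keep]
    return roots


def _level_crossing_times(times: np.ndarray, values: np.ndarray, level: float) -> np.ndarray:
    """Crossing times of a sampled curve with a constant level; when the
    level is never attained, the single nearest-approach time is returned."""
    crossings = find_intersections(DifferenceCurve(times, values), level)
    if len(crossings):
        return crossings
    dense = np.linspace(times[0], times[-1], 4001)
    approach = np.abs(np.interp(dense, times, values) - level)
    return np.asarray([dense[int(np.argmin(approach))]])


def _refined_peak_time(curve: TimeAttenuationCurve) -> float:
    """Peak time with sub-sample precision.

    A parabola through the maximum sample and its two neighbours gives the
    vertex time; on coarsely sampled curves this removes the frame-interval
    quantization of the raw argmax.  Falls back to the sample time at the
    boundary or for a degenerate (non-concave) triple.
    """
    i = int(np.argmax(curve.values))
    t, v = curve.times, curve.values
    if i == 0 or i == len(t) - 1:
        return float(t[i])
    # vertex of the parabola through three (possibly non-uniform) samples
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    v0, v1, v2 = v[i - 1], v[i], v[i + 1]
    denom = (t1 - t0) * (v1 - v2) - (t1 - t2) * (v1 - v0)
    if denom <= 0:
        return float(t1)
    num = (t1 - t0) ** 2 * (v1 - v2) - (t1 - t2) ** 2 * (v1 - v0)
    vertex = t1 - 0.5 * num / denom
    if not (t0 <= vertex <= t2):
        return float(t1)
    return float(vertex)


def _first_upward_crossing(curve: TimeAttenuationCurve, level: float, before: float) -> float:
    """First time the curve rises through ``level`` at or before ``before``."""
    t, v = curve.times, curve.values
    for i in range(len(t) - 1):
        if t[i] > before:
            break
        if v[i] < level <= v[i + 1]:
            return float(t[i] + (level - v[i]) * (t[i + 1] - t[i]) / (v[i + 1] - v[i]))
        if v[i] == level:
            return float(t[i])
    return float(t[0])


def classify_phase(
    t_est: float, aif: TimeAttenuationCurve, vof: TimeAttenuationCurve
) -> tuple[str, list, Landmarks]:
    """Assign a bolus phase to an estimated acquisition time.

    With tA the AIF peak time, tV the VOF peak time and t50 the first time
    the AIF exceeds half its peak enhancement:

    - ``early_arterial``  for t50 <= t_est < tA (and, flagged, t_est < t50)
    - ``mid_arterial``    for tA <= t_est < (tA + tV)/2
    - ``mid_to_venous``   for (tA + tV)/2 <= t_est < tV
    - ``delayed_venous``  for t_est >= tV

    Raises if the VOF peaks at or before the AIF, which is non-physiological.
    """
    t_a = _refined_peak_time(aif)
    t_v = _refined_peak_time(vof)
    if t_v <= t_a:
        raise ValueError(
            f"VOF peak ({t_v} s) does not follow AIF peak ({t_a} s); "
            "curves are non-physiological"
        )
    base = float(aif.values.min())
    half_level = base + 0.5 * (float(aif.values.max()) - base)
    t50 = _first_upward_crossing(aif, half_level, before=t_a)
    landmarks = Landmarks(t_a, t_v, t50)
    flags: list = []
    mid = 0.5 * (t_a + t_v)
    if t_est < t50:
        flags.append("pre-bolus estimate (before AIF half-peak upslope)")
        phase = "early_arterial"
    elif t_est < t_a:
        phase = "early_arterial"
    elif t_est < mid:
        phase = "mid_arterial"
    elif t_est < t_v:
        phase = "mid_to_venous"
    else:
        phase = "delayed_venous"
    return phase, flags, landmarks


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(values)]
    return out


def estimate_timing(
    ctp_aif: TimeAttenuationCurve,
    ctp_vof: TimeAttenuationCurve,
    cta_arterial: float,
    cta_venous: float,
    smoothing_width: int | None = None,
) -> PhaseEstimate:
    """Locate the CTA acquisition time on the CTP bolus time axis.

    The constant CTA difference (arterial − venous HU) is intersected with
    the CTP AIF − VOF difference curve.  When several crossings exist (the
    difference curve is generally non-monotone, so a level can be reached on
    both its upslope and downslope), the candidate most consistent with both
    raw ROI values is selected: each CTA value defines its own crossing
    times on its CTP curve, and the candidate minimizing the summed time
    distance to the nearest AIF-level and VOF-level crossings wins — a
    well-conditioned time-domain form of joint mismatch against both
    measured HU values.  When no crossing exists (level outside the sampled
    range), the time minimizing ``|difference(t) − level|`` is returned with
    a quality flag.
    """
    if len(ctp_aif.times) != len(ctp_vof.times) or not np.array_equal(
        ctp_aif.times, ctp_vof.times
    ):
        ctp_aif, ctp_vof = resample_to_common_grid(ctp_aif, ctp_vof)
    aif, vof = ctp_aif, ctp_vof
    if smoothing_width and smoothing_width > 1:
        aif = TimeAttenuationCurve(aif.times, _smooth(aif.values, smoothing_width), aif.label)
        vof = TimeAttenuationCurve(vof.times, _smooth(vof.values, smoothing_width), vof.label)
    diff = difference_curve(aif, vof)
    if np.ptp(diff.values) < 1e-9:
        raise EstimationError("flat AIF − VOF difference curve: no timing information")
    level = float(cta_arterial) - float(cta_venous)
    candidates = find_intersections(diff, level)
    flags: list = []
    if len(candidates) == 0:
        flags.append("level outside difference-curve range; nearest-approach fallback")
        dense = np.linspace(diff.times[0], diff.times[-1], 4001)
        t_est = float(dense[int(np.argmin(np.abs(diff.value_at(dense) - level)))])
    elif len(candidates) == 1:
        t_est = float(candidates[0])
    else:
        # Joint-consistency disambiguation in the time domain: each raw ROI
        # value defines its own set of level-crossing times on its curve, and
        # the selected candidate is the one closest to being a simultaneous
        # AIF and VOF crossing.  Comparing times rather than raw HU
        # mismatches keeps the rule well conditioned where the curves are
        # steep (a sub-sample timing error there costs tens of HU).
        t_a = _level_crossing_times(aif.times, aif.values, cta_arterial)
        t_v = _level_crossing_times(vof.times, vof.values, cta_venous)
        score = [
            float(np.min(np.abs(t - t_a)) + np.min(np.abs(t - t_v))) for t in candidates
        ]
        t_est = float(candidates[int(np.argmin(score))])
        flags.append(f"{len(candidates)} intersection candidates; joint-consistency selection")
    phase, pflags, landmarks = classify_phase(t_est, aif, vof)
    return PhaseEstimate(
        t_est=t_est,
        candidates=candidates,
        phase=phase,
        landmarks=landmarks,
        quality_flags=flags + pflags,
    )
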