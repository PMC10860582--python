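# Methods

`ctaphase` implements, end to end and on synthetic data with known ground
truth, the analysis chain used to ask when a single-phase CT angiogram (CTA)
was acquired on the contrast bolus, and how bolus phase, collateral quality
and reperfusion success shape the agreement between CTA-based ischaemic
lesion estimates, perfusion-derived core/penumbra volumes, and the final
infarct volume (FIV). This note documents the models, the parameter choices,
the numerical decisions, and what the synthetic experiments do and do not
demonstrate.

## The bolus model

The first-pass arterial input function (AIF) is a gamma-variate in
enhancement (HU above a pre-contrast baseline):

    C(t) = A ((t - t0)/(αβ))^α exp(α - (t - t0)/β),   t > t0,

normalized so that the peak equals `A` exactly at `t0 + αβ`. Defaults
(`t0 = 12 s`, `α = 3`, `β = 1.5 s`, `A = 180 HU`, baseline `40 HU`) give an
arterial peak at 16.5 s with a realistic rise time for a 50 mL injection at
5 mL/s, sampled at 2 s over 40 frames as in a standard cerebral CT-perfusion
(CTP) acquisition.

The venous output function (VOF) is the AIF delayed by a venous **onset
lag** (default 3.5 s) and convolved with a normalized **exponential
transit-time kernel** whose time constant is `(d − 1)·√α·β` for the
dispersion factor `d` (default 2.5, giving τ ≈ 3.9 s). This was a genuinely
open design point, and the exponential kernel was chosen over symmetric
(Gaussian) broadening deliberately: a symmetric kernel must carry the whole
arteriovenous lag in the onset delay, which leaves the venous curve exactly
flat throughout the early post-arterial-peak window. In that regime the
acquisition-time problem becomes two-valued — the mirrored times on the
arterial up- and downslope produce identical (arterial, venous) HU pairs to
within noise — and no estimator can resolve them. Physiologically the
venous sinus begins to enhance a few seconds after the artery, while most of
the ~7 s peak-to-peak lag and the flatter, right-skewed venous shape come
from capillary-bed dispersion; the exponential kernel reproduces exactly
that and keeps the estimation problem identifiable. Convolution with a
unit-area kernel preserves the injected contrast area (checked to 0.1%).

Tissue is a low-amplitude scaled copy of the AIF (5%); the whole-field mean
curve is therefore a shallow bolus-shaped bump, which is all the pipeline
asks of it (a qualitative surrogate for overall brain attenuation).

## The digital phantom

A 24×24×12 grid at 1×1×2 mm holds two ~33-voxel spherical vessel ROIs
(arterial and venous), a static 900 HU one-voxel shell on every border
standing in for the skull (base and vertex included), and tissue elsewhere.
The shell carries no contrast dynamics but anchors intensity-based motion
correction on all three axes, as bone does on real head CT; without it, a
correlation registration between a frame dominated by venous enhancement
and an arterial-dominant reference has no reason to prefer the identity
shift. Noise is additive Gaussian per voxel-frame, homoscedastic, seeded —
the simplest model that exercises every noise-facing code path; it has no
photon-statistics or streak structure, so noise-robustness results bound
well-behaved noise only.

The CTA snapshot evaluates the same continuous curves at one acquisition
time `t_acq` (recorded as ground truth) plus noise; noiseless snapshot
intensities equal the dynamic curves at `t_acq` exactly.

## Motion correction

Translation-only, integer-voxel, per frame against frame 0: the applied
shift maximizes normalized cross-correlation within a ±3 voxel search cube,
computed via FFT circular cross-correlation (a circular shift preserves a
frame's mean and variance, so plain-correlation argmax equals NCC argmax).
Scores within a relative 1e-9 of the maximum are treated as ties and
resolved toward the smallest shift, so a structureless correlation
landscape never invents motion; constant frames are flagged and left in
place. The circular (wrap-around) boundary is appropriate for small motion
with padded fields of view and is exact for the roll-injected motion used
in testing. Rotations and sub-voxel motion are out of scope — registration
is not this package's contribution, and the phantom tests only require
inverse-consistency with known integer displacements.

## Acquisition-time estimation

The AIF − VOF difference curve is a function of bolus time; the constant
arterial − venous difference measured on the CTA intersects it at the
acquisition time. Intersections are computed on the piecewise-linear
interpolant of the sampled difference curve — every bracketed crossing is
solved exactly, samples exactly on the level count once — with no implicit
smoothing (an optional moving average exists, default off).

A level generally crosses the difference curve twice (up- and downslope),
so a disambiguation rule is required. Selecting by raw HU mismatch
`|AIF(t) − a| + |VOF(t) − v|` at the candidates proved ill-conditioned on
2 s sampling: near the arterial peak the linear interpolant sits several HU
below the true curve, and on a steep slope a sub-sample timing offset costs
tens of HU, so the comparison is dominated by interpolation bias rather
than by the data. The implemented rule works in the time domain instead:
each measured CTA value defines its own level-crossing times on its CTP
curve, and the candidate minimizing the summed time-distance to the nearest
AIF-level and VOF-level crossing wins. It uses exactly the same information
(both raw ROI values), is deterministic, and is well conditioned precisely
where the HU form is not. When the level misses the sampled curve entirely
(tangency near the difference peak), the nearest-approach time is returned
with a quality flag.

Phase labels use landmark boundaries, in order: `early_arterial` from the
AIF half-peak upslope time to the AIF peak `tA`; `mid_arterial` from `tA`
to the midpoint of `tA` and the VOF peak `tV`; `mid_to_venous` from that
midpoint to `tV`; `delayed_venous` from `tV` on. Estimates before the
half-peak upslope are flagged pre-bolus. Peak times are refined by a
three-point parabolic fit around the sample argmax — the raw argmax is
quantized to the 2 s frame grid, which by itself misplaces boundary-adjacent
acquisitions by up to one frame. `tV ≤ tA` is rejected as non-physiological.
These boundaries are a reproducible interpretation of the four-phase
convention, not a measured fact; all estimates live on the CTP bolus time
axis, with no clock synchronization between the two acquisitions.

The "test-bolus + 12 s" protocol preset models the ascending-aorta test
bolus peaking 10 s before the cerebral arterial peak (earlier aortic
arrival plus the shorter test injection), so the scan lands ~2 s after the
arterial peak — in the mid-arterial phase — with optional Gaussian trigger
jitter (0.6 s in the experiments).

## Volumetry

Thresholded volumes are suprathreshold voxel count × voxel volume
(mm³/1000), no rounding until display. Core is rCBF ratio < 30% of normal;
penumbra is Tmax > 6 s; the hypoperfusion intensity ratio (HIR) is
volume(Tmax > 10 s) / volume(Tmax > 6 s) — the standard definition, nested
by construction so HIR ∈ [0, 1] — dichotomized at 0.5 (good < 0.5 ≤ poor).
Lesion probability maps are binarized at p ≥ 0.5; 26-connected components
are kept only if their volume strictly exceeds 0.1 mL and their
majority voxel lies in the ipsilateral hemisphere outside the cerebellum
(exact ties resolve toward keeping). The per-component reading of the
volume filter, the inclusive binarization, the 26-connectivity and the
majority vote are pinned here because each is a reasonable free choice a
reimplementation must fix to be reproducible.

## Statistics

- Pearson r with the Fisher-z 95% CI (SE `1/√(n−3)`) and the exact
  t-distribution P on n−2 df (scipy).
- ICC(2,1): two-way random-effects, absolute-agreement, single-measures,
  computed from the two-way ANOVA mean squares; CI by the Satterthwaite-df
  F interval (McGraw & Wong); P from `F = MSR/MSE` on `(n−1, (n−1)(k−1))`
  df. This is the conventional ICC for two-method comparison; unlike r it
  penalizes systematic offsets. Tests cross-check it against pingouin's
  two-way random absolute-agreement ICC and an exact-rational ANOVA oracle.
- OLS of the estimate on the reference (scipy linregress).
- Bland-Altman with empirical 2.5th/97.5th percentile limits of the
  differences (estimate − reference, so positive means overestimation);
  percentiles use linear interpolation between order statistics everywhere,
  including IQRs — pinned for bit-reproducibility.
- Shapiro-Wilk (3 ≤ n ≤ 5000) as the normality gate justifying medians/IQR
  and rank tests for volume data; Kruskal-Wallis with tie correction and
  the chi-square P across strata. Significance is read two-sided at 0.05
  with no multiple-testing correction across strata (deliberately, to
  mirror the analysis convention this pipeline reproduces). At very small
  groups (3+3) the chi-square P is anti-conservative relative to the exact
  permutation distribution (0.0495 vs 0.10 for complete separation); the
  validation suite asserts exactly this boundary behaviour.

## The synthetic cohort

Each of `n_patients` (default 121) draws a latent collateral quality
c ~ U(0,1) that drives everything a collateral-dependent cohort needs:
HIR ≈ 1 − c (Gaussian jitter, clipped to [0,1]); Miteff grade by terciles
of c (1 poor / 2 moderate / 3 good); a lognormal core volume scaled up for
poor collaterals; penumbra = core + lognormal at-risk volume (median
45 mL). TICI success is Bernoulli(0.81); the CTA-based estimate is
`core + λ(penumbra − core) + N(0, 10 mL)` floored at 0 with λ = 0.5 — the
estimate sits between core and penumbra; FIV converts a baseline 25%
(successful) or 65% (futile) of the at-risk tissue, scaled by
`1 + (collateral_effect − 1)(1 − c)` and clipped, with collateral_effect 2.
LKW-to-imaging times are lognormal (median 240 min, capped at 24 h), ~2.5%
unknown; ~20% are wake-up strokes with sleep/wake clock times. These
defaults reproduce the qualitative structure of a real anterior-circulation
thrombectomy cohort: overestimation relative to FIV in reperfused patients,
larger infarcts with poor collaterals under both Miteff and HIR
stratifications, and plausible volume medians. The generator makes no
claim to calibrated variances or between-variable correlations beyond the
single latent collateral axis, so passing cohort tests demonstrate
directional recovery, not quantitative reproduction of any real cohort.

## Stratified report

`build_report` crosses three stratifiers (Miteff 1/2/3, HIR </≥ 0.5, TICI
futile {0,1,2a} / successful {2b,2c,3}) with three presentation windows
(all, <6 h, 6–24 h from last known well; the 6–24 h bound is closed at
1440 min; unknown times are excluded from windowed strata and counted).
Wake-up strokes take the sleep–wake midpoint as presumed LKW, wrapping
midnight; equal sleep and wake times read as 24 h apart. Per stratum it
reports n, Pearson + ICC with CIs (only when n ≥ 4 — smaller strata are
flagged not-evaluable, never dropped), and median (IQR) volumes; per cell,
Kruskal-Wallis across strata for both the estimate and FIV; per window,
Bland-Altman + OLS of the estimate against core and penumbra. The report
is a pure function of the input table — identical CSV in, byte-identical
JSON out.

## Problem sizes and validation scope

Validation experiments run at the sizes the package documents as its study
conditions: 50 noiseless + 100 noisy (5 HU) phantoms for timing recovery,
200 sweep points for phase monotonicity, 50 phantoms for the protocol
preset, 100 seeded datasets against brute-force statistical oracles, 2000
and 1000 replicates for the Kruskal-Wallis type-I and Fisher-z coverage
calibrations, 50 random maps for volumetry exactness, and a 500-patient
cohort for directional recovery. On one CPU the whole set completes in a
few seconds. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); derived seeds use `SeedSequence` and stay
below 2³¹.

## Known limitations

- No scanner physics: no beam hardening, partial volume, photon noise, or
  DICOM; volumes travel as NIfTI with spacing in the affine.
- Registration is integer translation with periodic boundaries; real rigid
  motion includes rotation and sub-voxel components.
- The four phase boundaries are a documented convention, not a clinical
  standard; other reasonable landmark choices shift labels near boundaries.
- The ambiguity analysis above implies a floor: acquisitions in windows
  where arterial and venous values jointly fail to discriminate the two
  difference-curve branches (e.g. deep in the washout tail) recover with
  errors up to about one frame interval, noiseless.
- The cohort generator encodes one latent collateral axis; it cannot
  falsify analyses that depend on richer covariance structure.
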