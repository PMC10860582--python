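# ctaphase

Bolus-phase timing of single-phase CT angiography against CT-perfusion
time-attenuation curves, perfusion-based infarct volumetry, and stratified
agreement statistics — with a synthetic phantom and cohort generator so the
whole pipeline runs, and is tested, without any patient data.

## The problem

In acute ischaemic stroke, CTA-based methods (including CNNs) that estimate
the infarct core tend to overestimate it relative to the final infarct
volume (FIV). A key suspect is acquisition timing: a single-phase CTA
freezes the contrast bolus at one unknown moment, and a scan in the
mid-arterial phase sees hypoperfused-but-salvageable tissue (penumbra) as
unenhanced, inflating the apparent core. `ctaphase` provides the tooling to
investigate this:

- **Timing**: place the CTA on the CTP bolus time axis. With the arterial
  input function AIF(t) and venous output function VOF(t) from the dynamic
  CTP study, the constant CTA difference `a − v` satisfies
  `AIF(t) − VOF(t) = a − v` at the acquisition time; the package finds all
  crossings of the piecewise-linear difference curve, disambiguates them
  using both raw ROI values, and assigns one of four bolus phases
  (early-arterial → mid-arterial → mid-to-venous → delayed-venous) from
  the curve landmarks.
- **Volumetry**: infarct core (rCBF < 30%), penumbra (Tmax > 6 s), the
  hypoperfusion intensity ratio HIR = V(Tmax>10 s)/V(Tmax>6 s) as a
  collateral surrogate, and lesion volumes from probability maps with the
  inclusion rules p ≥ 0.5, volume > 0.1 mL, ipsilateral non-cerebellar.
- **Agreement statistics**: Pearson r (Fisher-z 95% CI), ICC(2,1) from the
  two-way ANOVA mean squares with its F-based CI, OLS, Bland-Altman with
  percentile limits, Shapiro-Wilk gating, Kruskal-Wallis — assembled into
  a stratified report (collateral grade × HIR × reperfusion success ×
  presentation-time window).
- **Synthetic data**: gamma-variate bolus phantoms with delayed/dispersed
  venous curves, CTA snapshots with ground-truth acquisition times,
  perfusion maps with prescribed core/penumbra/HIR, and patient cohorts in
  which the CTA estimate lies between core and penumbra and the FIV depends
  on collaterals and reperfusion.

See `docs/methods.md` for the models, defaults and numerical decisions.

## Worked example

Simulate a phantom, acquire a CTA under a "test-bolus peak + 12 s"
protocol, and recover when it was taken:

```python
from ctaphase import (BolusParams, PhantomGeometry, simulate_ctp_series,
                      simulate_cta_snapshot, preset_test_bolus_t_acq,
                      extract_roi_curve, cta_roi_values, estimate_timing)

params = BolusParams(seed=7)            # 40 frames @ 2 s, 5 HU noise
geom = PhantomGeometry()
series, truth = simulate_ctp_series(params, geom)

aif = extract_roi_curve(series, geom.arterial_roi())
vof = extract_roi_curve(series, geom.venous_roi())

t_acq = preset_test_bolus_t_acq(params)          # 18.5 s (ground truth)
cta = simulate_cta_snapshot(params, geom, t_acq)
a, v = cta_roi_values(cta, geom.arterial_roi(), geom.venous_roi())

est = estimate_timing(aif, vof, a, v)
print(round(est.t_est, 2), est.phase)
```

This prints:

```
18.46 mid_arterial
```

The CTA ROI values were (182.9, 77.8) HU; the difference level 105.1 HU
crossed the AIF − VOF curve at 14.48 s (arterial upslope) and 18.46 s
(downslope), and the joint-consistency rule picked the downslope crossing —
0.04 s from the true acquisition time, 1.8 s after the arterial peak
(16.62 s): a mid-arterial scan, the regime in which CTA-based core
estimates absorb penumbra.

Cohort level, from a shell:

```sh
ctaphase pipeline demo --seed 5 --n 121 --out demo/
```

```
futile: n=28, estimate median 37.9 mL, FIV median 57.5 mL
successful: n=93, estimate median 40.7 mL, FIV median 34.4 mL
report written to demo
```

Among successfully reperfused patients the median CTA-based estimate
(40.7 mL) exceeds the median final infarct (34.4 mL) — the overestimation
signature of mid-arterial acquisition — while futile reperfusion lets the
infarct grow past the estimate. `demo/` contains the stratified correlation
and median-volume tables (`table2.csv`, `table3.csv`), Bland-Altman/OLS
numbers against core and penumbra (`figure3_stats.json`), and the full
report JSON.

Other subcommands: `ctaphase simulate ctp|cta|maps|cohort`,
`ctaphase tac extract|motion`, `ctaphase timing`, `ctaphase volumes
prob|perfusion`, `ctaphase pipeline run`.

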