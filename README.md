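# octaqa

Intraeye **quadrant-asymmetry (QA)** analysis of OCTA vessel metrics over
the ETDRS parafoveal ring.

Optical coherence tomography angiography (OCTA) measures retinal perfusion
without dye.  Two standard densities are computed on the superficial
retinal layer over the parafoveal ring (the 1–3 mm-diameter annulus around
the fovea, split into superior, inferior, nasal and temporal quadrants):

* **VLD** — vessel length density: skeletonized vessel length per unit
  area, mm⁻¹;
* **PD** — perfusion density: fraction of area covered by perfused
  vasculature.

Raw densities are hard to compare between eyes because age, axial length,
refraction and scan quality all shift them.  QA is an *intraeye* statistic
that cancels those confounders:

```
QA(eye, metric) = max_q metric[q] − min_q metric[q],   q ∈ {S, I, N, T}
```

In central retinal vein occlusion (CRVO), ischemic eyes accumulate
capillary dropout scattered unevenly over the parafovea, so QA rises even
though no particular quadrant is preferentially affected.  An elevated
QA — especially of PD — separates ischemic from non-ischemic CRVO.

The package is aimed at reading-center analysts and OCTA methods
researchers: it takes calibrated en-face angiograms (PNG/TIFF + JSON
sidecar) or tidy per-quadrant CSV tables, and produces QA tables, group
summaries, two-group contrasts (mean difference ± pooled SE and
Mann-Whitney U), empirical CDFs, per-quadrant comparisons, and an
eye-fixed-effects quadrant regression.  Synthetic cohort and image
generators with retained ground truth make every stage testable without
patient data.  See `docs/methods.md` for the statistical details.

## Worked example

Simulate a cohort at the study's group sizes (27 control, 21 non-ischemic,
10 ischemic eyes), analyze it, and print the report:

```bash
octaqa simulate --out demo/sim --seed 7
octaqa analyze --metrics demo/sim/metrics.csv --out demo/analysis
octaqa report --report demo/analysis/report.json
```

```
QA group summaries (mean +/- SD):
  vld control        n=27  3.206 +/- 1.618
  vld non_ischemic   n=21  3.383 +/- 1.749
  vld ischemic       n=10  4.283 +/- 2.189
   pd control        n=27  0.071 +/- 0.028
   pd non_ischemic   n=21  0.058 +/- 0.021
   pd ischemic       n=10  0.102 +/- 0.051
QA contrasts (mean difference +/- pooled SE, Mann-Whitney p):
  vld ischemic vs non_ischemic: 0.900 +/- 0.729, p=0.348
  vld ischemic vs control: 1.077 +/- 0.660, p=0.180
  vld control vs non_ischemic: -0.177 +/- 0.488, p=0.650
   pd ischemic vs non_ischemic: 0.043 +/- 0.013, p=0.035 *
   pd ischemic vs control: 0.031 +/- 0.013, p=0.148
   pd control vs non_ischemic: 0.012 +/- 0.007, p=0.165
Quadrant regression (superior = reference):
  vld inferior  coef +2.726 SE 0.978 p=0.007
  vld nasal     coef +0.353 SE 0.978 p=0.719
  vld temporal  coef +1.481 SE 0.978 p=0.133
   pd inferior  coef +0.063 SE 0.019 p=0.001
   pd nasal     coef +0.010 SE 0.019 p=0.600
   pd temporal  coef +0.034 SE 0.019 p=0.081
```

Reading this single simulated cohort: ischemic eyes show the highest mean
QA for both metrics, and the QA(PD) contrast between ischemic and
non-ischemic eyes reaches significance (p = 0.035) at these small group
sizes, while QA(VLD) does not — the PD signal is the stronger
discriminator.  The regression coefficients are quadrant × ischemic
interactions: with α = 0.05 and no correction, one quadrant pops in this
draw; across many simulated cohorts they center on zero because the
generator spreads dropout exchangeably across quadrants.  The analysis
directory also contains `qa.csv`, the summary/contrast/regression CSVs,
ECDF and per-quadrant figures, and `resolved_config.yaml` for provenance.

The image-level pipeline works the same way from rasters:

```bash
octaqa simulate --out demo/imgs --seed 2 --level images --n-images 6
octaqa metrics --images demo/imgs --out demo/metrics
octaqa qa --metrics demo/metrics/metrics.csv --out demo/qa.csv
```

Library use mirrors the CLI: `build_etdrs_grid`, `quadrant_metrics`,
`quadrant_asymmetry`, `compare_groups`, `quadrant_fixed_effects_regression`
and the generators in `octaqa.synthetic_data`.

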