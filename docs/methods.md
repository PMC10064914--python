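# Methods

## The quadrant-asymmetry statistic

Optical coherence tomography angiography (OCTA) quantifies retinal
perfusion on an en-face flow image of the superficial retinal layer (SRL).
Two standard densities are computed over regions of the ETDRS grid:

* **vessel length density (VLD)** — total length of the skeletonized
  (1-pixel-wide) perfused vasculature per unit area, mm⁻¹ (mm/mm²);
* **perfusion density (PD)** — fraction of area covered by the binarized
  perfused vasculature, dimensionless in [0, 1].

Raw densities are confounded by eye-level covariates (age, axial length,
refraction, signal strength), which makes between-eye and longitudinal
comparisons noisy.  **Quadrant asymmetry (QA)** sidesteps this: for one eye
and one metric, QA = max − min of the metric over the four parafoveal
quadrants (superior, inferior, nasal, temporal).  Both extremes come from
the same scan, so any eye-level additive confounder cancels exactly
(QA is translation-invariant and scales linearly with the metric).

In central retinal vein occlusion (CRVO), ischemic eyes accumulate
capillary non-perfusion scattered over the parafovea; uneven dropout across
quadrants inflates QA, which is how QA separates ischemic from non-ischemic
CRVO even when no single quadrant is preferentially affected.

## Geometry

The parafoveal ring is the annulus 0.5 mm ≤ r < 1.5 mm from the fovea
center (inner/outer diameters 1 and 3 mm).  A pixel belongs to the annulus
iff its center satisfies the half-open radial rule, which makes the four
quadrant masks an exact partition (asserted per-pixel in tests).  The
default calibration is the 3 × 3 mm, 245 × 245 scan raster
(pixel ≈ 12.2 µm); pixel size must be isotropic — anisotropic input is
rejected rather than silently resampled.

Quadrant boundaries are the two 45° diagonals.  A pixel exactly on a
diagonal is assigned to the **vertical wedge** of the adjacent pair
(superior or inferior).  We chose this tie-break over a rotational
(clockwise) rule because it is mirror-symmetric in both axes, which buys
two exact identities:

* flipping the image horizontally and toggling OD↔OS reproduces every mask
  bit-for-bit (laterality involution);
* OD and OS grids on the same image are pure relabelings
  (nasal↔temporal).

The cost is that the 90°-rotation neighbour-mapping holds only up to the
diagonal pixels (~0.3% of the annulus at 245²) rather than exactly.
Orientation is configurable (`row0-superior` default; `row0-inferior` for
devices that export flipped); nasal is image-left for OD, image-right for
OS.  The fovea center comes from metadata — automatic foveal avascular-zone
detection is out of scope since the device centers scans on the fovea.

## Vessel maps and densities

Device binarization is proprietary, so the package provides two documented
alternatives: local-mean adaptive thresholding (default; block 31 px,
offset −10% of the dynamic range, which compensates the point-spread blur
that otherwise widens vessels) and global Otsu.  Connected components
< 5 px are removed before skeletonization so speckle does not inflate VLD.
A constant image binarizes to all-background with a logged warning.

Skeletons come from topological thinning (scikit-image).  Skeleton length
is a step sum over every unordered 8-adjacent pixel pair: axial pairs count
one pixel size, diagonal pairs √2 pixel sizes, isolated pixels one pixel
size.  Plain pixel counting would under-measure diagonal vessels by ~29%.
Known limitation: this chain-code estimator carries an angle-dependent bias
(up to ~8% for oblique lines) that does not vanish with resolution, so VLD
is reproducible across resolutions only to within ~8%, while PD converges
to well under 3%.  Thinning is also not exactly mirror-equivariant, so the
laterality involution propagates exactly for PD but only to ~a few percent
for VLD.

Per quadrant q: `pd[q] = |binary ∧ mask_q| / |mask_q|` and
`vld[q] = skeleton length within mask_q / quadrant area`.  Scans with
signal strength ≤ 7 (device scale 1–10) are flagged and excluded from
pipeline runs, mirroring the usual inclusion rule.

## Cohort statistics

* **Group summaries**: n, mean, sample SD (n−1) of QA per group
  (control / non-ischemic / ischemic) and metric.
* **Mean difference ± pooled SE**: sp² = ((nₐ−1)sₐ² + (n_b−1)s_b²)/(nₐ+n_b−2),
  SE = sp·√(1/nₐ+1/n_b).  Applied to the published per-group summaries this
  reproduces the published contrast table to printed precision (one SE
  differs by one unit in the third decimal, consistent with the inputs
  being printed rounded).
* **Mann-Whitney U** (two-sided), U = #{x>y} + half-ties.  `exact` mode uses
  the permutation null: a counting recursion for tie-free data, full
  enumeration of the C(n+m, n) labelings when ties are present (falling
  back to the approximation with a log message beyond an enumeration cap);
  `normal_approx` uses the tie-corrected normal approximation with
  continuity correction.  The p-value is 2·min(P(U≤u), P(U≥u)) capped at 1.
  Degenerate samples (all values identical) give p = 1, logged.
* **ECDFs** are right-continuous with F(max)=1; the right-shift helper
  checks pointwise dominance over the joint support.
* **Per-quadrant comparisons** pool control + non-ischemic eyes against
  ischemic eyes and Mann-Whitney-test the raw quadrant values, one test per
  quadrant.
* **Eye-fixed-effects regression**: OLS of quadrant values on one intercept
  per eye plus quadrant dummies (superior = reference).  The default
  `interaction` variant fits CRVO eyes with quadrant × ischemic interaction
  terms — eye intercepts absorb all eye-level variation including the group
  main effect, so each reported coefficient asks whether a quadrant is
  *differentially* depressed in ischemic versus non-ischemic eyes.  The
  `within_ischemic` variant fits plain quadrant dummies on ischemic eyes
  only.  Both are exposed because the underlying model description admits
  either reading; conventional OLS standard errors and t-tests are
  reported.  Rank deficiency (e.g. a group absent) raises an error naming
  the unidentified term.
* No multiple-testing adjustment by default (a Holm helper is available);
  α = 0.05 two-sided throughout.

## Synthetic data

No patient images or per-eye tables are publicly deposited, so the package
ships two generators that define its test conditions.

**Metric level.**  Per eye, quadrant values are
`base[group] + eye_effect − S·J·severity[group]·w_q` with
S ~ Gamma(18, 1/18) (eye-level dropout magnitude, unit mean),
J ~ Gamma(18, 1/18) per metric, and w ~ Dirichlet(1,1,1,1) the spatial
allocation of dropout across quadrants, shared by both metrics.  QA is then
exactly S·J·severity·(max w − min w): all asymmetry flows through uneven
dropout allocation, so zero severity or a perfectly even allocation
(concentration → ∞) gives QA = 0, and group mean QA is monotone in
severity.  The allocation is exchangeable across quadrants, matching the
finding that no quadrant is preferentially affected.

Defaults are calibrated once to the published cohort: group sizes 27/21/10
eyes; severity = published group QA mean / E[range of w] (= 0.45833 for
Dirichlet(1,1,1,1)); the two Gamma shapes set the QA coefficient of
variation to ≈ 0.50, matching all three published groups.  Base levels
(VLD ≈ 18.5/17.5/13 mm⁻¹, PD ≈ 0.40/0.38/0.28 observed after mean dropout)
give the raw-value group separation seen in per-quadrant comparisons.  The
roster emulates the paired design — CRVO patients contribute a diseased eye
and usually their fellow eye as control, with one monocular patient, one
bilateral patient and one orphan control — yielding 58 eyes from 31
patients at the defaults.

What the metric-level generator does **not** emulate: measurement error
correlated between neighbouring quadrants, signal-strength gradients,
media-opacity artifacts, or any preferred quadrant.  Passing tests
therefore show that the statistics recover the structure this model
encodes, not that real CRVO cohorts behave this way.

A note on finite samples: the ischemic QA distribution stochastically
dominates the pooled control + non-ischemic distribution in population by
construction, but with 10 ischemic versus 48 other eyes the two empirical
CDFs cross in roughly half of simulated cohorts — everywhere-dominance of
small-sample ECDFs is a much stronger event than dominance in
distribution.

**Image level.**  Scenes are a handful of branching arcades radiating from
the fovea plus a Poisson mesh of short capillary segments (125 segments/mm²,
lengths 73–171 µm, width 25 µm), rasterized at the scan resolution;
per-quadrant dropout removes whole capillary segments (keyed on the
segment midpoint's quadrant), mimicking capillary non-perfusion rather than
salt-and-pepper erosion.  Intensity is the vessel raster under a small
Gaussian point spread (σ = 0.7 px) plus additive noise (σ = 8% of peak).
These constants were set once so that healthy scenes land in realistic
ranges (PD ≈ 0.30–0.40, VLD ≈ 15–21 mm⁻¹ at 245²) and default binarization
recovers the ground-truth raster with Dice ≥ 0.9.  Ground truth (the
post-dropout, noise-free raster and its quadrant metrics) is retained for
every scene.  Image-pipeline tests run at 128² to stay fast; statistical
tests use the metric level.

## Problem sizes and numerics

Simulation-based tests use 50–500 generated cohorts (58 eyes each) or
50 image seeds at 128²; the acceptance script averages 200 cohorts and one
245² scene.  All generators are pure functions of (config, seed); a single
seed drives every run.  Ties in argmax/argmin quadrants are broken in the
fixed order superior, inferior, nasal, temporal.  PD is stored as a
fraction in [0, 1] throughout (the published QA(PD) magnitudes, 0.06–0.11,
are fractions, not percentage points) and rendered as % only in reports.
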