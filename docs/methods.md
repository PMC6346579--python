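# Methods

This note documents the models implemented by `wmh_bullseye`, the defaults
of the synthetic generator, the numerical choices, and what the synthetic
testbed does and does not establish about real data.

## Bullseye parcellation

**Depth field.** For every white matter (WM) or basal ganglia (BG) voxel,
normalized depth is

    f = d_v / (d_v + d_c),   f ∈ [0, 1]

where `d_v` and `d_c` are Euclidean distances (in mm, voxel-size aware;
`scipy.ndimage.distance_transform_edt`) to the nearest ventricular-mask and
cortical-sheet voxel. `f` is undefined (NaN) outside WM+BG. An
alternative construction uses a Laplacian potential between the two
surfaces; the distance ratio is adopted here because it is cheap, exact for
concentric geometry, and reproduces "equidistant layers" by definition.

**Layers.** Depth is binned into four equidistant layers with half-open
bins and a closed top bin: [0,.25)→1, [.25,.5)→2, [.5,.75)→3, [.75,1]→4.
Layer 1 is periventricular, layers 2–3 are deep white matter, layer 4 is
juxtacortical. The closed top bin ensures voxels touching the cortex are
juxtacortical and no voxel is orphaned.

**Segments.** Nine segments: frontal/parietal/temporal/occipital × L/R
(labels 11–18) plus the basal ganglia complex (label 3), which receives
layers exactly like the lobes — required for the 9 × 4 = 36-region
partition. Region code = 4·segment_index + layer, a bijection with
(segment, layer). Infratentorial structures are absent by construction
(the analysis is supratentorial only).

## Volumetry

Regional WMH volume is `voxel_volume × Σ p(v)` over the region's voxels of
the lesion-probability map — probabilistic (soft) volumetry, no cut-off.
Global volume is the sum over all coded voxels, so regional volumes are
additive to the global one by construction. TIV counts every
non-background voxel (tissue + ventricles/CSF). Outcomes are carried in
cm³ and as 100·cm³/TIV (%TIV); all association analyses use %TIV.

## CAIDE-I

Points (model without APOE): age <47 → 0, 47–53 → 3, >53 → 4; education
≥10 y → 0, 7–9 y → 2, <7 y → 3; male → 1; SBP >140 mmHg → 2; BMI >30 → 2;
hypercholesterolemia → 2 (standing in for total cholesterol >6.5 mmol/l
when only diagnosis/medication flags are available); physically inactive
→ 1. Total ∈ [0, 15]. Education enters in years; fractional years use the
same thresholds.

The 20-year dementia probability is logistic in the total score,

    risk% = 100 / (1 + exp(−(−6.596160 + 0.398967·score))).

The two coefficients are fixed by a least-squares fit of the logit line
through the three published (score, risk) quantile pairs (4, 0.67 %),
(6, 1.47 %), (8, 3.22 %); the fitted expression reproduces all three to
two decimals, and is strictly increasing with risk(0) ≈ 0.14 % and
risk(15) ≈ 35.2 %.

Classifier boundaries are strict (`>`, never `≥`) wherever the defining
criterion reads "above"/"more than": composite hypertension =
self-report ∨ medication ∨ SBP > 140 (the CAIDE scale itself uses only the
measured-pressure condition); active = moderate > 150 ∨ vigorous > 75
min/week; a parental AD history counts only with onset < 75 years.
Missing activity or family-history data propagate as NaN and are excluded
per-analysis, never imputed.

## Association engine

* Continuous predictors: Spearman's ρ (average ranks for ties).
* Dichotomous predictors: tie-corrected normal-approximation Mann–Whitney
  z as the permuted statistic; Cohen's d (pooled SD, raw %TIV scale) as
  the reported effect size.
* Dichotomous × dichotomous cross-correlations: χ² with the signed φ.
* Group predictors run as pairwise contrasts against a reference group
  (APOE vs ε3/ε3, excluding ε2 homozygotes as too few; family history vs
  no-history).

**Permutation p.** `p = #{|T_perm| ≥ |T_obs|} / n_perm` with
`n_perm = 10,000` by default; permutations re-assign the outcome vector to
the predictors (shuffles without resampling). A zero count is floored at
`1/n_perm` — an exact zero is unreportable. Both statistics used are
affine in the permuted rank vector, so the engine evaluates all
permutations by matrix products; the generic callable path
(`permutation_p`) is retained and the two are cross-checked in tests.

**Covariate models.** Model 1 is direct. Models 2 (age) and 3
(hypertension) rank-transform the outcome — and a continuous predictor —
and residualize on the rank-transformed covariate by least squares before
testing; permutations shuffle the residualized outcome (a Freedman–Lane
style scheme). The correlation of the two residual vectors is exactly the
textbook first-order partial Spearman coefficient. For Cohen's d under
Models 2/3, the raw %TIV values are OLS-residualized on the raw covariate.
Residualizing both sides (not only the outcome) is a deliberate choice:
it makes the statistic symmetric and matches the partial-correlation
interpretation.

**FDR families.** Benjamini–Hochberg within each family: one family = the
36 regional tests of one predictor × model (the bullseye maps); a separate
family = the global rows across predictors within one model (the
global-association table). Significance is q < 0.05.

**CIs.** 95 % percentile bootstrap (1,000 resamples; stratified by group
for d). Degenerate inputs (constant outcome in a region, an empty group in
a contrast) yield NaN rows that are excluded from the FDR family rather
than aborting a run.

## Synthetic generator

**Cohort.** One latent multivariate normal (Gaussian copula) couples age,
sex, education, SBP, BMI, cholesterol propensity, activity propensity,
hypertension-diagnosis propensity and total WMH load. Pairwise targets
are specified as Spearman correlations and converted to latent Pearson
values by `r = 2·sin(πρ/6)`; the matrix is checked for positive
semidefiniteness. Defaults (all chosen once, by calibration against the
published cohort description, and then frozen):

| quantity | default | rationale |
|---|---|---|
| invited / analyzable | 608 → 561 | exclusion cascade 13 non-consent, 20 invalid scans, 14 quality removals |
| age | truncated normal, mean 58, SD 9.7, range [45, 75] | median 58, IQR ≈ 51–64 |
| sex | 38.9 % male | cohort table |
| education | normal(14, 4.45) y | median 14, IQR 11–17 |
| SBP | normal(125, 15) mmHg | P(SBP > 140) ≈ 16 % |
| BMI | log-normal(ln 26.4, 0.15) | median 26.4, IQR 24.0–29.4 |
| hypercholesterolemia | 30.5 % | cohort table |
| hypertension diagnosis | 17 % latent prevalence | composite (dx ∨ med ∨ SBP>140) ≈ 26.2 % |
| activity | moderate log-normal(ln 240, 0.9), vigorous log-normal(ln 45, 1.2), 8 % missing | ≈ 71 % active among observed |
| WMH load | log-normal(ln 1.94, 0.88) cm³ | median 1.94, severely right-skewed |
| TIV | normal(1386, 120) cm³ | median %TIV = 0.14 |
| age–WMH rank link | ρ = 0.22 | the published global age effect |
| APOE, family history | categorical at published frequencies | drawn independently of the copula |

The WMH distribution family and the per-region load law are not published;
the log-normal and the weight-vector placement below are calibrated
choices, not inferences.

**Brains.** The phantom is a stylized concentric geometry at 64³ × 1 mm by
default: ventricular ball (15 % of the half-extent), WM shell (to 80 %),
2-voxel cortical sheet, eight angular lobar wedges and a BG cone spanning
the full shell depth so all 36 regions are non-empty. Anisotropic voxels
are supported (distances are computed in mm) but not default. Its TIV
(~0.08 L at 64³) is far below a physiological ~1.4 L, so the lesion
planter preserves each participant's WMH *fraction of TIV*: planted volume
= (wmh_total/tiv from the registry) × phantom TIV. Rank-based statistics
and %TIV outcomes are invariant to this miniaturisation; absolute-cm³
calibration is carried by the registry columns. Lesions are planted as
probability increments of 0.25 on voxels sampled with probability
proportional to the 36 per-region weights (uniform within a region),
clipped at 1. Default weights emphasize periventricular layers (3 : 1.5 :
1 : 0.75) and the occipital lobes (×1.5), with BG at ×0.5.

**What the generator does not emulate.** Anatomy (no gyri, no lesion
confluence or shape), registration error, segmentation noise, site
effects, and — most importantly — *regionally differentiated* risk-factor
links: the default generator draws one global severity per participant, so
every region's load is a noisy share of it and a predictor linked to the
global load associates with all regions at once. Regional specificity
appears only when a run plants a localized weight vector (as the
planted-frontal recovery test does). Passing tests therefore demonstrate
correctness of the machinery and statistical calibration, not that real
lesion topography would be recovered. Attenuated realized correlations
for thresholded flags (hypertension diagnosis, cholesterol, activity) are
expected: copula targets apply to the latent scale, and fidelity (±0.03 at
n = 5000) is asserted for continuous columns only.

## Numerical choices and problem sizes

* Distances in physical mm; parcellation independent of voxel visiting
  order; all randomness through `numpy.random.Generator` seeded from
  explicit parameters (per-participant streams derive from the seed and
  the participant id via CRC32, kept below 2³¹).
* Permutation comparisons use a 1e-12 tolerance to absorb float ties.
* Cohort-scale simulation tests and the acceptance script use a 48³
  phantom and 100 replicate cohorts of n = 561 — sizes at which the
  Monte-Carlo SE of the mean recovered ρ (~0.004) is well below the
  tolerance of interest; the null-calibration suite uses 1,000 replicates
  at n_perm = 1,000, n = 40.
* The bullseye figure orders sectors FL, FR, PL, PR, OL, OR, TL, TR, BG
  clockwise from the top, ring 1 innermost; cells are colored only at
  q < 0.05 on a symmetric diverging map. The geometry of the published
  figure was never specified numerically; this layout is the package's
  convention.

## Known limitations

* The CAIDE logistic is anchored to three printed quantile pairs; the
  original publication's exact coefficients may differ in later decimals.
* Cohen's d is computed on raw (skewed) %TIV values — deliberately, to
  match the reported effect-size convention for dichotomous predictors —
  so d is not a monotone transform of the rank-based z it accompanies.
* The exclusion cascade records reasons but removes rows at random;
  selective drop-out is not modeled.
* TIV is drawn independently of sex and age; real intracranial volume is
  not.
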