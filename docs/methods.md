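# Methods

This note documents the models, conventions and design choices behind
`lungdens`: what the density indices assume, what the synthetic
generators emulate (and deliberately do not), and the numerical
decisions that affect results.

## Density indices

All indices are functions of the HU values of lung-mask voxels; no
weighting, trimming or resampling is applied.

- **MLD** is the arithmetic mean HU over the selected mask region.
  Whole-lung values are computed over the *union* of both lungs
  (voxel-weighted), not as the average of per-side MLDs; per-side values
  are always reported alongside, so either convention can be recovered.
- **MLDD = EXP MLD − INS MLD.** The sign is fixed so a normally
  densifying lung is positive (e.g. −659 − (−788) = +129 HU). Note that
  averaging per-subject MLDDs over a cohort is not the same as
  differencing the rounded group-mean MLDs; group summaries computed
  either way can differ in the last decimal.
- **E/I ratios** are 100·EXP/INS, computed on signed quantities. For MLD
  both values are negative in practice, so the ratio is a positive
  percentage below (healthy) or near (trapping) 100%.
- **Threshold fractions** use strict inequalities: LAA counts voxels
  with HU **<** threshold, HAA counts HU **>** threshold, and a voxel
  exactly at the threshold counts for neither. This symmetric rule makes
  the three-bin partition (below t₁ / [t₁,t₂] / above t₂) sum to exactly
  100% and is what the brute-force oracle tests assert. LAA thresholds
  default to {−850, −900, −950} HU, HAA to {−600, −650} HU, all measured
  on the expiratory phase.
- HU values outside the 12-bit plausibility window [−1024, 3071] produce
  a counted warning, never a silent clip — synthetic noise tails
  legitimately cross the boundary.
- Voxel indices are 0-based; no index requires world coordinates. The
  first array axis is the subject left-right axis and mask label 1 is
  subject-left; mirrored inputs are the caller's responsibility.

`simple_lung_segment` (threshold below −400 HU, border-connected air
removal, largest one or two components, laterality by centroid) is a
convenience for phantoms and clean volumes only; clinical segmentation
quality is out of scope and masks are normally an input.

## Paired-phase phantom

The phantom embeds two ellipsoidal lungs of Gaussian parenchyma
N(μ, σ²) in uniform soft tissue (default +40 HU). Expiration does two
things:

1. **geometry** — the semi-axes shrink by ratio^(1/3), so the expiratory
   lattice is a geometric subset of the inspiratory one and the E/I
   volume equals the configured ratio up to voxelization;
2. **density** — each expiratory voxel reuses the inspiratory density
   draw at its position; non-trapped voxels gain +Δ HU, trapped voxels
   gain nothing. Trapped membership is the fraction-p nearest-neighbour
   shell around a small number of random blob seeds (mosaic pattern),
   recomputed on each phase's lattice with exact count ⌊p·n⌋.

No registration or deformation is modelled: none of the indices needs
voxel correspondence, and the subset construction makes the zero-noise,
zero-trapping case an exact +Δ shift at matched voxels, which the tests
exploit.

Closed-form expectations (the ground-truth oracle): INS MLD = μ,
EXP MLD = μ + (1−p)·Δ, MLDD = (1−p)·Δ, E/I volume = 100·ratio, and each
expiratory threshold fraction is a two-component mixture

E_t = 100·[ p·Φ((−t−μ)/σ_tot) + (1−p)·Φ((−t−μ−Δ)/σ_tot) ],

with σ_tot² = σ_parenchyma² + σ_noise². These ignore edge/partial-volume
voxels; the documented discretization bound on E/I volume is one voxel
shell, 100·(surface voxels)/(total inspiratory voxels), and recovery
tests assert agreement within 3 Monte-Carlo standard errors at ≥10⁵
parenchymal voxels. The default worked example (μ=−880, σ=30, Δ=150,
p=0.3) gives EXP MLD −775 HU and E900 ≈ 7.6%, verified against a 10⁶-draw
Monte-Carlo oracle.

Ages enter through a linear trend on the inspiratory mean,
μ(age) = μ_ins + (−15 HU/year)·(age − 10), reflecting the decrease of
pediatric parenchymal density with lung growth; the reference age of 10
years sits at the cohort medians so the default μ_ins is the
reference-age value.

Defaults (Δ = 130 HU, ratio 0.6, p = 0) reproduce a healthy control's
MLDD ≈ 130 HU; `bo_like_spec` (p = 0.5, ratio 0.73) lands near the BO
group's MLDD ≈ 65 HU.

All randomness derives from one top-level seed through named substreams
(geometry / density / noise / cohort), so changing one stage's draw
count cannot silently shift another's.

## Cohort simulator

Subject tables are drawn per group from normal marginals whose default
means/SDs are the published control (n=30) and BO (n=51) pediatric group
summaries for every PFT and LDI. Dependence is imposed with a Gaussian
copula: a target Spearman ρ is converted to the copula's Pearson
parameter by r = 2·sin(πρ/6). The default structure is identity plus a
small set of physiologically signed pairs (MLDD/E-I indices with FEV1,
expiratory LAA fractions with sRaw, HAA fractions and EXP MLD with RV),
kept as disjoint stars so the matrix is provably positive semi-definite;
a non-PSD request is rejected with the nearest valid matrix in the
message. These pair values are implementer assumptions — the published
tables report regression coefficients, not a correlation matrix.

Out-of-range values are **truncated, not resampled**: E-fractions and
E/I ratios to [0, 100], percent-of-predicted PFTs at 0 below. At the
default parameters truncation materially affects only variables whose
mean sits within about one SD of a bound (E900/E950 in particular, which
are near-zero in controls); there it creates ties at the bound and
attenuates rank correlations, which is why the copula-recovery test uses
an unbounded pair. Ages are truncated normals on [3, 18] years with the
location solved so the *truncated* median equals the group target
(12.5 y control, 9.0 y BO) and scale IQR/1.349; sexes are Bernoulli at
the published male fractions.

Missingness is modality-level per subject: the whole spirometry block
(FVC, FEV1, FEV1/FVC, FEF25-75) or plethysmography/diffusion block (TLC,
RV, sRaw, DLCO, VA) is absent with the group-specific published rates
(20%/25.5% and 20%/37.3%); assigning DLCO/VA to the plethysmography rate
is an assumption, as no separate rate is published.

Because each variable follows its own marginal, within-row arithmetic
identities between LDIs (MLDD = EXP−INS MLD; E/I MLD = 100·EXP/INS) hold
only in distribution, not per subject. Simulated tables are for
group-level statistical behaviour — power, AUC, calibration — not for
re-deriving one index from another.

What passing tests on these synthetics do *not* show: real parenchyma is
not two-component Gaussian (vessels, airways, gravity-dependent
gradients), real expiratory physiology correlates volume loss with
densification within subject, scanner noise is not white, and real LDI
distributions are skewed where the simulator clips. Calibration results
transfer to real cohorts only to the extent those features are
second-order for rank-based statistics.

## Statistical evaluation

- **Group comparisons**: two-sided Mann-Whitney for continuous variables
  (scipy's exact method where applicable), chi-square with Yates
  continuity correction for categorical tables — the correction is what
  reproduces the published gender p-value (0.993; uncorrected gives
  0.805).
- **Regressions**: OLS and ML logistic fits via statsmodels, always
  adjusted for age (years, untransformed) and sex (single male
  indicator). Backward elimination drops the largest-p predictor until
  all retained p < 0.05 (covariates never dropped); all-subset selection
  minimizes AIC. Coefficients are unstandardized with 95% CIs; in an
  exact (zero-residual) fit the CI collapses onto the estimate by
  convention. Rank-deficient designs raise an error naming the collinear
  columns; (quasi-)separated logistic fits raise a separation diagnosis
  — estimates are never silently divergent. Odds ratios are per unit of
  the predictor with Wald CIs. The LDI-vs-PFT table treats the LDI as
  outcome and each PFT as predictor (switchable), and the logistic table
  fits one predictor plus covariates per row — a joint model of all
  collinear indices at n≈81 would not be estimable.
- **ROC**: AUC by the rank estimator (ties 0.5), identical to the
  trapezoidal area under the empirical curve; 95% CI by DeLong
  (structural components), with a seeded 2000-resample bootstrap
  available. Orientation is auto-selected so AUC ≥ 0.5 and recorded.
  The Youden cutoff is an exhaustive scan over observed values with the
  inclusive-on-disease-side rule; ties prefer higher specificity, then
  the more extreme cutoff — deterministic and reproducible from the
  integer confusion counts that are always reported. n_used is the
  complete-case count of the variable, reported per analysis.
- Two-sided α = 0.05 throughout, no multiplicity correction by default
  (a stay-threshold option exists), matching common practice in studies
  of this size.

## Problem sizes

Test and acceptance runs use phantoms of ~10⁴ (unit tests) to ~1.2×10⁵
(recovery tests) parenchymal voxels, 200 cohort replicates for power
checks, 10⁵-draw Monte Carlo for binormal AUC comparisons, and 100
replicates at n=500–1000 for planted-parameter recovery; these sizes put
Monte-Carlo error well below the tested tolerances while keeping the
whole suite in the seconds-to-minutes range.

## Known limitations

- HU calibration, rescale slopes, kernels and dose are assumed handled
  upstream; inputs are taken as calibrated HU in NIfTI (volumes stored
  as int16 on disk, float64 in memory).
- The threshold segmenter is not a clinical lung segmentation.
- No deformable registration, parametric response mapping or
  percentile-density indices; E/I and threshold fractions only.
- The copula defaults are assumptions, not published estimates; studies
  needing a specific dependence structure should set
  `rank_correlations` explicitly.
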