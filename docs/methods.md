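# Methods

## Model

For each atlas region, collect the regional mean of every imaging modality
into a data matrix `Y` with one row per subject and one column per
modality (here: a task-fMRI F-contrast summary, a resting-state residual
mean-square summary, and a gray-matter density summary). The multivariate
general linear model is

    Y = X B + U

with design matrix `X = [1, g, age, sex, TIV]`, where `g` is a 0/1
diagnostic-group indicator and age, sex and total intracranial volume are
nuisance covariates. `B` is estimated by ordinary least squares
(minimum-norm via `lstsq` when `X` is numerically rank-deficient, rank
tolerance `1e-10 x` the largest singular value).

The group effect is tested through the error and hypothesis
sums-of-squares-and-cross-products matrices

    E = (Y - X B)'(Y - X B)
    H = (C B)' [C (X'X)^- C']^{-1} (C B),   C = contrast selecting g  (q = 1)

and Wilks' lambda `Λ = det(E) / det(E + H)`, computed through a Cholesky
factor of `E` and `slogdet` of `E + H`, clamped to `(0, 1]`. Two reference
distributions are reported:

- **Bartlett chi-square**: `χ² = -(n - r - (p - q + 1)/2) ln Λ` with
  `df = p·q` (n subjects, r = rank of X, p modalities, q hypothesis df).
  At the default study geometry (n = 44, r = 5, p = 3, q = 1) the scale is
  37.5 and df = 3.
- **Rao's F**: the standard transformation of `Λ^{1/s}`, exact under
  normality when `min(p, q) <= 2`, which always holds here (q = 1).

Canonical vectors solve the generalized eigenproblem `H v = λ E v`
(`scipy.linalg.eigh(H, E)`). Eigenvalues are clipped at 0 and sorted
nonincreasing; `Λ = Π 1/(1+λᵢ)` is asserted internally on every region to
within 1e-8. Each vector is scaled to unit Euclidean norm and its sign is
fixed so the largest-magnitude component is positive — signs of such
decompositions are inherently arbitrary, so downstream interpretation
should use magnitudes or fix signs by convention, as here. Exact
eigenvalue ties (within 1e-12) are ordered by lexicographic comparison of
the vectors so output is deterministic.

Across regions, raw p-values are adjusted with Benjamini–Hochberg FDR by
default (Bonferroni and no correction selectable). FDR is the standard
choice for screening ~119 regions; both methods are always available so
either reading of a "corrected" threshold is reproducible. Regions that
cannot be tested (zero-variance column, singular `E`) are excluded,
logged, and counted — output regions + exclusions always equal input
regions.

## Standardization

Each modality column of `Y` is z-scored (sample SD, ddof = 1) before
fitting, on by default. Wilks' lambda, the chi-square and the p-value are
invariant to any nonsingular affine transform of the columns of `Y` (the
test statistics are functions of `E^{-1}H` eigenvalues), so
standardization changes only the canonical weights, making them
comparable across modalities with different units. A flag disables it.

## Published reference values

A published study of this design (44 subjects: 19 schizophrenia, 25
depression; 119 Neuromorphometrics regions; 3 modalities) reports, for 43
regions, a p-value, a chi-square statistic and a 3-component canonical
vector. Two conventions are validated against that table:

- the chi-square → p mapping at df = 3 reproduces the printed p-values at
  4-decimal rounding (42 of 43 rows exactly; one row differs by one unit
  in the fourth decimal, consistent with print rounding);
- the printed canonical vectors have squared-component sums within 5e-4
  of 1, matching this package's unit-norm output convention.

The chi-square statistics and canonical-vector components themselves
**cannot be recomputed** here: they derive from subject-level MRI volumes
that were not released. They are therefore used only for the two
convention checks above, and the pipeline's statistical behaviour is
validated instead by the property checks below.

## Synthetic cohort generator

The generator emulates the study structure, not its imaging physics:

- **Group sizes** default to 19 + 25; regions to 119; modalities to 3.
- **Demographics**: age ~ Uniform(18, 65) years; sex ~ Bernoulli(0.5)
  coded 0/1 (female/male); TIV ~ Normal(1400, 110) mL + 100 mL for males.
  Confounds are independent of diagnosis by default (the emulated study's
  groups did not differ demographically); `group_confound_shift` adds a
  group/confound correlation to exercise adjustment.
- **Features** per region: multivariate Gaussian noise with covariance
  `Σ` (default exchangeable correlation 0.3, unit variances — a
  deliberately non-diagonal default so the multivariate code path is
  exercised) plus confound contributions. `confound_coeffs` act on
  z-scored confounds (age SD 13.57 y, sex half-range 0.5, TIV SD 120 mL),
  defaults 0.3/0.2/0.3 per modality — modest, realistic loadings.
- **Planted effect**: group 2's mean is shifted by
  `effect_size × effect_direction × sqrt(diag(Σ))`, i.e. the effect size
  is in per-modality noise-SD units and comparable across covariance
  choices.

What the generator does not emulate: voxel-level spatial autocorrelation,
scanner artifacts, non-Gaussian feature distributions, and site/sequence
effects. Passing the checks below shows the statistics are computed
correctly and calibrated under the generator's assumptions; it does not
certify behaviour on real MRI features that violate them (the emulated
study does not report within-group feature distributions, so Gaussianity
is an assumption of the generator, not a claim about that data).

## Validation properties and problem sizes

- **Null calibration**: 2000 independent null regions at n = 19 + 25 with
  correlated noise; the raw p < 0.05 rate must lie in [0.035, 0.065]
  (binomial 99.9% band around 0.05 is roughly ±0.016 at this size).
- **Permutation agreement**: on 20 study-size instances, the Bartlett p
  and a 10,000-draw permutation p (independent oracle: Frisch–Waugh
  residualization plus the rank-one determinant identity, numpy only)
  agree within 0.02 — Monte-Carlo SE at p ≈ 0.05 is ~0.002.
- **Direction recovery**: 200 replicates, δ = 1.5, n = 200/group,
  *uncorrelated* noise; the leading canonical vector's |cosine| with the
  planted direction must be ≥ 0.95 in ≥ 95% of replicates. Uncorrelated
  noise is essential here: the population canonical vector is proportional
  to `Σ⁻¹ μ`, which is collinear with the planted mean shift `μ` only for
  diagonal `Σ`; under correlated noise the estimator correctly converges
  to `Σ⁻¹ μ`, not `μ`, and a cosine criterion against `μ` would measure
  the noise structure, not an error.
- **Oracle equivalence**: 50 random instances comparing OLS with the
  explicit normal equations, `H` with the reduced-minus-full SSCP
  identity, and affine/confound invariance of `Λ` (tolerance 1e-8).
- **Paint/extract inverse**: writing each region's statistic into the
  atlas volume and re-extracting regional means returns the statistic to
  float64 precision (averaging k identical doubles can differ by an ulp).

These sizes keep the full validation suite within a few minutes on one
CPU while leaving each check statistically sharp.

## Numerical and design choices

- Group coding is a single two-level indicator (q = 1). The published
  table's (chi-square, p) pairs are consistent with df = 3 = p·q only for
  q = 1, so diagnostic subgroups (unipolar vs bipolar depression) are not
  separately contrasted.
- Bartlett's scaled `-ln Λ` is used for the chi-square (rather than the
  unscaled `-(n-r) ln Λ`); the difference is O(1/n) and the scaled form is
  the standard one. Rao's F is computed alongside because an F-test of
  Wilks' lambda is the other canonical reading; both appear in output.
- p-values are stored at full precision; 4-decimal display matches the
  usual reporting style.
- `region_means` excludes NaN voxels from means (zero is meaningful in
  F-contrast maps); an all-NaN region yields NaN plus a warning. Volumes
  must share grid and affine with the atlas; mismatches are hard errors,
  never resampled.
- A single common atlas is assumed; per-subject atlases can be supplied by
  running extraction per subject with different atlas files.

## Limitations

- Only Wilks' lambda is implemented (no Pillai/Hotelling–Lawley/Roy).
- No voxel-wise multivariate maps, surface meshes, or cluster-extent
  correction.
- The Bartlett approximation is asymptotic; at very small n the Rao F
  p-value (exact for q = 1 under normality) is preferable, and both are
  reported.
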