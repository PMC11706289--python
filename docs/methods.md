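# Methods

This note documents the statistical model behind each stage of
`aphasiamap`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions that were genuinely open.

## Dimension scoring

A rating profile assigns an integer 0–4 to each of 23 connected-speech
features. The packaged feature–dimension map holds 29 (feature,
dimension, sign) entries over those 23 features — nine for Paraphasia,
eight for Logopenia, seven for Agrammatism, five for Motor speech — so
six features load on more than one dimension and contribute to each
independently. The published source of this assignment is a figure plus
supplementary loading matrix that are not machine-readable here, so the
packaged map is a reconstruction from the feature definitions that
satisfies all published count constraints exactly; it is shipped as JSON
data, not code, and any user with the original matrix can substitute it
(`FeatureDimensionMap.from_json`). One entry (Paragrammatism within
Agrammatism) is reverse-scored (sign −1), exercising the mirrored
rescaling path r → 100 − 25r.

Ratings are rescaled 0→0, 1→25, 2→50, 3→75, 4→100 and averaged per
dimension. Missing ratings are an error: no published imputation rule
exists, and silently imputing ordinal clinical ratings would be worse
than failing.

The eligibility filter tests its criteria in a fixed order (untestable →
QAB ≥ 8.9 → right-hemisphere dominance → sample < 3 min → < 10 words/min
→ jargon-only → stereotypy-only → unintelligible-only → no speech
attempt) and reports the first failure, so any roster is partitioned
exactly into included plus per-reason excluded counts.

## Psychometrics

* **ICC(A,1)** — two-way random-effects, absolute-agreement,
  single-rater form, computed from the ANOVA mean squares
  (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n). Single-rater (not
  average-rater) was chosen because clinical use involves one rater.
  Joint pooling of (participant, feature) pairs as rows is the default
  for an across-feature agreement coefficient; per-feature ICCs are
  available by calling the function per column. Non-positive estimates
  are reported as 0 with a warning. Qualitative bins: poor < .40 ≤ fair
  < .60 ≤ good < .75 ≤ excellent.
* **BCa bootstrap** — bias-correction z₀ from the proportion of
  replicates below the point estimate (with a half-count continuity
  adjustment and clipping to avoid infinite quantiles), acceleration
  from jackknife skewness. Degenerate bootstrap distributions collapse
  to a point interval with a warning rather than producing NaNs. All
  CIs in the package route through this one implementation.
* **Polyserial correlation** — two-step estimator: thresholds fixed at
  inverse-normal cumulative proportions of the ordinal margin, then ρ
  maximizing the conditional likelihood of the ordinal given the
  standardized continuous variable under the latent bivariate-normal
  model. Two-step (rather than full ML) is robust at the n ≈ 23–118
  scale this package targets; bootstrap resamples that lose ordinal
  levels fall back to the full-sample estimate rather than failing.
* **ω_t** — one factor per dimension's item block by default (the
  coefficient describes the reliability of one unit-weight score).
  Extraction is minimum-residual via iterated principal axes:
  communalities start at the squared multiple correlations (largest
  absolute row correlation when R is singular) and are iterated to a
  fixed point of the reduced-correlation eigenproblem. ω_t = 1 − Σψ /
  [Σ_f (Σ_i λ_if)² + Σψ]. Heywood communalities are clipped to 1
  (uniqueness 0) with a warning.

## ROI analysis

OLS with intercept of each dimension score on the four ROI lesion
volumes in raw cm³ (no transform; the per-cm³ coefficient scale is the
interpretable one). Per-ROI inference is an unadjusted two-tailed t-test
at α = .05 — matching how such coefficient tables are conventionally
reported — with Holm correction available behind a flag. Cohen's f² is
computed by the full-vs-reduced R² definition; the partial-correlation
identity f² = t²/df_resid is used as a cross-check in the tests, not as
the implementation. Pillai's trace is computed per single-coefficient
hypothesis (H = (Lβ̂)'[L(X'X)⁻¹L']⁻¹(Lβ̂), E = residual SSCP,
V = tr[H(H+E)⁻¹]) with the exact F transform for one hypothesis degree
of freedom, F = V/(1−V) · (ν−m+1)/m; it reduces to the squared t-test
with one outcome and is invariant to invertible recombination of the
outcomes (both properties are tested, alongside a cross-check against
statsmodels' MANOVA).

## Voxel-wise lesion-symptom mapping

Binary masks are smoothed with a Gaussian of 8 mm FWHM (σ per axis =
FWHM / (edge · 2√(2 ln 2)); zero-padded boundaries). The smoothed,
continuous value is the default per-voxel regressor; smoothed masks are
re-binarized at 0.5 only for coverage counting and volumetry, because no
re-binarization rule for the regressor is standard and the continuous
value preserves information (a binary-regressor switch exists). Voxels
lesioned in fewer than ceil(0.05 n) participants are excluded (NaN in
the t-map, never cluster members), as are covered voxels whose regressor
has zero variance.

At each retained voxel: OLS of the score on [intercept, voxel value,
total lesion cm³], df = n − 3, one-tailed test of β > 0 at p < .01
(damage can only worsen a 0–100 impairment score; the one-tailed form
encodes that direction). Suprathreshold voxels are grouped by
26-connectivity by default (the common lesion-mapping convention; 6 and
18 available) with deterministic labelling (largest first, ties by
lexicographically smallest member index).

Family-wise correction: the behavioural score vector is shuffled across
participants (mask–covariate pairing untouched), the maximum cluster
size recorded per permutation, and each observed cluster assigned
corrected p = (1 + #{null ≥ size}) / (1 + n_perm) — the add-one
estimator, so p = 0 is never reported and the smallest attainable p is
1/(n_perm + 1). Plain score shuffling is the default scheme; a
Freedman–Lane option (permute covariate residuals and add back the
covariate fit) is provided because it has better small-sample properties
when the covariate is correlated with the scores. For speed, the
covariate block is residualized out of the scores and all voxel
regressors once (Frisch–Waugh), reducing each permutation to a single
matrix–vector product plus one connected-component pass.

## Overlap and bias

DSC between significant-cluster masks, with BCa CIs obtained by
resampling voxels of the union with replacement. Re-running the entire
permutation pipeline per bootstrap replicate (resampling participants)
would be the other defensible unit; voxel resampling was chosen as the
computationally feasible interpretation and is stated here as a choice.
The multivariate summary is the mean upper-triangle pairwise DSC plus
the all-maps conjunction; empty maps are dropped with a warning.

The bias map runs only for pairs with non-negligible overlap — DSC or
its bootstrap CI reaching 0.4 (the "fair" bin) — and standardizes each
map's t statistics to 0–100 by percentile rank within that map's own
significant voxels (so the bias is invariant to any monotone transform
of either t-map; constant maps collapse to rank 50); min–max scaling is
available as an alternative. Bias = standardized(A) − standardized(B) on
the overlap, antisymmetric by construction, with positive/negative peak
locations reported in world mm.

## Synthetic cohorts

The generator emulates the statistical structure of an acute post-stroke
aphasia sample, not its anatomy:

* **Territory** — a hemisphere-like ellipsoid confined to one half of
  the grid (~36% of voxels), standing in for a middle-cerebral-artery
  territory. Toy grid 24³ at 4 mm (tests, calibration studies);
  full-size preset 64³ at 2 mm.
* **Lesions** — target volumes from a log-normal with arithmetic mean
  34.3 and sd 38.2 cm³ (the reported lesion-extent distribution of the
  kind of cohort emulated), grown from a random territory voxel by
  uniformly random accretion of face-adjacent territory voxels. Region
  growing (rather than ellipsoids) produces the irregular, connected,
  territory-clipped shapes that make cluster inference honest. Targets
  exceeding the territory are clipped with a warning.
* **Behaviour** — latent score_d = intercept_d + Σ_r β_{r,d}·vol_r +
  ε_d, ε multivariate normal with per-dimension sd 12 and an
  all-positive correlation matrix strongest among the three non-fluency
  dimensions; clipped to [0, 100] with the clipping fraction logged in
  the manifest. Default βs concentrate Paraphasia on the Temporal ROI
  and the non-fluency dimensions on the Frontoparietal ROI, at the
  points-per-cm³ order of magnitude such cohorts show; intercepts near
  the observed dimension means.
* **Ratings** — a feature's latent value is its dimension's latent score
  plus Gaussian feature noise (sd 5), mirrored for reverse-scored
  features, then cut at thresholds (12.5, 37.5, 62.5, 87.5) — the
  midpoints of the rescale bins, making the rating the nearest-level
  quantization of the latent score. Additional raters perturb the
  feature latent by (1 − agreement) · 15 sd, so agreement = 1 duplicates
  raters exactly. Note that a feature loading on two dimensions is
  generated from its first dimension's latent only (a rating is a
  property of the feature, not of the pair), so with the packaged map
  the rebuilt dimension scores are quantized mixtures — the strict
  one-step quantization bound holds for maps without cross-loading
  features, and is tested that way.
* **Eligibility** — by default every simulated participant passes;
  exact per-reason exclusion counts can be configured and are assigned
  deterministically so the filter's output counts reproduce them.

All randomness flows from the single config seed through one generator;
cohorts are bit-identical across runs, and the manifest records the seed
and a config hash.

What passing tests on these cohorts do **not** show: realism of lesion
anatomy or spatial covariance of real stroke (no vascular tree, no white
matter), rater behaviour beyond exchangeable Gaussian perturbation, or
any claim that planted effect sizes match real effect sizes. They do
show that the estimators are unbiased, calibrated and correctly
implemented under a known generative model.

## Problem sizes used in the test and calibration suites

Calibration studies run on the 24³/4 mm grid with n = 60 and 500
permutations per cohort (200 cohorts for the family-wise error study),
and parameter-recovery studies at n = 118 with 100 replicates; these
sizes give binomial/Monte-Carlo error small enough for the asserted
bands while keeping the default suite fast on one CPU. The distribution-
matching check for lesion volumes uses 500 lesions on the full-size
grid.

## Known limitations

* Native-space lesion delineation, registration/normalization and
  ROI derivation from functional activation maps are out of scope;
  images are assumed co-registered on a common grid, and the synthetic
  ROI atlas is a geometric partition, not anatomy.
* The packaged feature–dimension map is a reconstruction (see above);
  analyses of real datasets should substitute the canonical map.
* Smoothing loses mass at grid boundaries (zero padding); keep ≥5 voxels
  of padding around lesions for mass-conservation-sensitive uses.
* The permutation test assumes exchangeability of scores across
  participants under the null; with strong covariate–score dependence
  prefer the Freedman–Lane scheme.
* Anatomical labelling of peaks (gyrus names) is narrative in the source
  literature and deliberately not computed here.
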