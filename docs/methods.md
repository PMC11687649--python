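# Methods

This note documents the models, algorithms, numerical choices and
limitations of `healthycore` in enough detail to audit or extend them.

## Data model

A `FeatureTable` is an n-subjects × n-features matrix with one
descriptor per column — (atlas region, hemisphere, measure) — and one
metadata record per row (site, diagnostic group HC/EM/CM, age, sex).
The measure determines the units bijectively (area↔mm², thickness↔mm,
volume↔mm³). The full Desikan-Killiany table has 204 columns (34
regions × 2 hemispheres × 3 measures). After any load, columns are
reordered to the canonical sorted (hemisphere, region, measure) order,
so feature order never depends on file layout. Missing cells are a hard
error by default; optional per-feature median imputation must be
requested explicitly. FreeSurfer `aparcstats2table` output is read by
merging the three per-measure tables on subject ID, dropping aggregate
columns (eTIV, MeanThickness, WhiteSurfArea, …) and keeping unknown
region labels with a warning, so other parcellations still load.

## Geodesic Flow Kernel

Subspaces are fitted by SVD of the centered data; because area,
thickness and volume live on scales three orders of magnitude apart,
the pipeline z-scores features (pooled-HC statistics) before any PCA —
unscaled PCA would be volume-dominated. The subspace dimension *d*
defaults to the smallest dimension explaining 90% of source variance,
capped at ⌊min(n₁−1, n₂−1, D/2)⌋ so the orthogonal complement can hold
the geodesic's companion directions.

With principal angles θᵢ = arccos σᵢ(P₁ᵀP₂) (singular values clipped to
[0, 1]), the geodesic frame is A = P₁U₁ together with unit companions
C in the orthogonal complement, and Φ(t) = A cos(tΘ) + C sin(tΘ). The
kernel G = ∫₀¹ Φ(t)Φ(t)ᵀ dt follows in closed form with the diagonal
integrals

    Λ₁ = 1/2 + sin 2θ / 4θ,  Λ₂ = sin²θ / 2θ,  Λ₃ = 1/2 − sin 2θ / 4θ.

Numerical choices: for θ < 10⁻⁴ the integrals switch to series
expansions (Λ₁ ≈ 1 − θ²/3, Λ₂ ≈ θ/2, Λ₃ ≈ θ²/3); zero-angle companion
directions are set to zero (their integrand vanishes); G is symmetrized
after assembly; the PSD square root clips eigenvalues below 10⁻¹² of
the largest to zero so rank-deficiency is exact in the transformed
data. When d > D/2 the closed form is degenerate and the quadrature
path is used with a warning.

The quadrature oracle integrates Φ(t)Φ(t)ᵀ by composite Simpson rule
over the explicitly interpolated geodesic. Simpson (error O(n⁻⁴),
~10⁻⁹ at 200 steps) rather than trapezoid (~5·10⁻⁶ at 200 steps) keeps
the oracle's own error far below the 10⁻⁶ agreement the closed form is
held to, so a disagreement indicts the closed-form constants, not the
integrator. The oracle shares only the geodesic construction with the
closed form, not the Λ integrals it validates.

## MMD

Biased estimator: mean(K₁₁) + mean(K₂₂) − 2·mean(K₁₂) ≥ 0. Unbiased
U-statistic: within-sample diagonals excluded; slightly negative values
under the null are expected. Kernels: linear or RBF, in Euclidean or
GFK space (GFK-space computations go through the symmetric square root
G^{1/2}; for the RBF variant the bandwidth defaults to the median
pairwise distance of the pooled mapped sample). The default comparison
kernel is linear-GFK: "MMD in GFK space" is most directly the G-inner
product, and the linear case makes MMD² = ‖G^{1/2}(x̄₁ − x̄₂)‖²
hand-checkable. The permutation test relabels the pooled sample
preserving the group sizes and uses the add-one p-value
(1 + #{perm ≥ obs})/(1 + B), which never returns zero.

## Healthy-core selection

Greedy backward elimination is the reference strategy: at each step,
for every currently retained subject the cross-site MMD² without that
subject is computed (O(1) per candidate via incremental Gram-matrix
bookkeeping), the minimizing subject is removed, and the trajectory
(pool size, MMD²) is recorded. Stop rules: `target_size` (total
retained), `mmd_pvalue` (stop when the permutation p exceeds α,
default 0.10 with the unbiased estimator — "indistinguishable" is the
stated goal), or `mmd_threshold`. The GFK is computed once from the
full pools by default; refitting it during the search changes the
comparison space mid-stream and is available only as an explicit
sensitivity option. Ties are broken by a seeded shuffle; the seed
affects nothing else except permutation draws, so reruns are
bit-identical. If a rule cannot fire before `min_core_per_site` is
reached, the best state so far is returned with `stopped_early` set. A
greedy forward variant (grow from the best-matched seeds) is provided
for comparison.

Caution on the unbiased estimator: a greedy search can push the
U-statistic well below zero by over-fitting the cross terms. This does
not harm membership recovery at realistic separations (the acceptance
checks measure precision/recall ≈ 0.89 against planted truth), but the
final MMD² magnitude should be read against its permutation null, not
against zero.

## Synthetic study generator

The generator emulates a two-site migraine morphometry study:

    x = baseline + site_shift·1[site 2] + group effect
        + off-core shift·1[non-core HC] + low-rank correlated noise.

* **Scales.** Per-measure baseline means/SDs (area 2500 ± 326 mm²,
  thickness 2.5 ± 0.177 mm, volume 7000 ± 1038 mm³) are set so the
  average |mean difference| between disjoint 21-subject subsets of one
  site lands at typical FreeSurfer regional magnitudes (tens of mm²,
  ~0.04 mm, hundreds of mm³). `calibrate_to_paper_scales` exposes the
  closed-form mapping: w = √(4σ²/πn) inverts to σ; the cross-site
  excess gives the shift SD via s = √(π(c² − w²)/2).
* **Site effect**: a broad, weak random per-feature mean shift, default
  SD 0.1 per-feature-SD. It is kept small relative to the HC
  heterogeneity deliberately: the premise of a *shared* core is that
  the cross-site HC discrepancy is driven chiefly by heterogeneous
  individuals; a large uniform offset applied to every subject is
  unfixable by any subset selection.
* **Disease effects**: mean shifts of 0.5 (chronic) and 0.35 (episodic)
  per-feature SD on a random 30% of features, chronic ≥ episodic
  enforced (the more severe state). These magnitudes put within-site
  test AUC in the 0.8–0.95 range at the default sample sizes.
* **HC heterogeneity**: a fraction π (default 0.5) of each site's HCs
  is drawn from the shared core distribution; the rest carry an
  off-core mean shift along a site-specific random direction
  (per-feature RMS 2 per-feature-SD) *plus* 0.7 of the chronic-disease
  effect vector. The disease-direction component implements the
  clinical premise that HC heterogeneity includes latent,
  not-yet-manifest disease; it is what makes heterogeneity harmful to
  cross-site classification rather than merely orthogonal noise.
* **Noise**: 10 shared low-rank factors carrying 50% of each marginal
  variance (morphometric features are strongly correlated) plus
  diagonal noise; generation is O(nD).
* **Covariates**: site-specific sex imbalance (72% vs 45% female) and
  age distributions; default group sizes are 54/51/15 (site 1) and
  42/8/26 (site 2) HC/EM/CM.
* **Seeding**: one master seed; per-site, per-group and structure
  streams derived deterministically, so same seed ⇒ bit-identical
  tables and truth.

What the generator does *not* emulate: non-Gaussian marginals,
scanner-specific covariance rotations, age/sex effects on features,
longitudinal structure, or FreeSurfer segmentation failures. Passing
tests show the machinery is correct and the method behaves as claimed
*under the planted mechanism*; they are not evidence about any
particular real cohort.

## Cohort diagnostics

Welch t (two-sided; variance equality is itself under test, so the
pooled-variance t would be inconsistent), two-sample KS, two-sided
variance-ratio F, and Ansari–Bradley (exact null for small samples via
scipy, normal approximation otherwise) per feature, with
Benjamini–Hochberg FDR. Features constant in both cohorts are flagged
and given p = 1. Sex-balanced subsampling draws, per replicate, the
largest common per-level count from both cohorts and reruns the
battery; because replicates within one cohort pair share subjects,
Monte-Carlo uncertainty of the rejection rate is governed by the
number of cohort draws, not replicates — the tests and the acceptance
script therefore average over fresh cohort pairs.

The average-mean-difference summary compares disjoint n_sub=21 subsets
(within site 1, within site 2, within the pooled sample, and across
sites) over 100 replicates, averaged per measure family. The
`mean_variance` adjustment standardizes every feature by the *pooled*
mean/SD: per-cohort standardization would zero out every cross-site
subsample-mean difference by construction and could never show a
residual site effect, whereas pooled standardization preserves the
pattern on a dimensionless scale (and quantitatively matches the
behaviour such adjusted tables show, including the thickness value
growing rather than shrinking, since its raw SD is below one).

## Experiments

Binary HC-vs-patient classification with L1 logistic regression
(liblinear), RBF-SVM, random forest, and XGBoost. Hyperparameters are
tuned by an in-package sequential model-based optimizer: random
exploration then a fixed-length-scale Matern-5/2 GP surrogate with
expected-improvement acquisition over the unit hypercube, log-scaled
where appropriate, deterministic given the seed (default budget 30
evaluations; the test suite and acceptance script use 5 to stay within
desk-scale runtimes). The objective is validation AUC.

Because HC/patient groups are strongly imbalanced (e.g. 54 vs 15),
models train with balanced class weights, and each tuned model's raw
scores are passed through a one-dimensional logistic calibration fitted
on the validation split with balanced class weights. Metrics at the
0.5 threshold (accuracy, specificity, sensitivity, F1, with attached
confusion counts) are then prevalence-robust; AUC uses the midrank tie
convention. Without this calibration, cross-site accuracy comparisons
mostly measure each test set's class prevalence.

Designs: Experiment I splits one site 60/20/20 into train/val/test
(stratified); Experiment II trains/validates (75/25) on one site and
tests on the whole of the other; Experiment III replaces the HC pools
with core members. Its leakage rule: the core spans both sites, so
training uses the training site's core HCs plus the test site's core
members *not* reserved for testing (half, redrawn per repeat), and
testing uses the reserved test-site core members against the test
site's patients — no subject ever appears on both sides. Each design
is repeated under 5 seeded re-splits by default (2 in the reduced-
budget harness) and metrics are averaged; summary tables add an
Average row computed as the arithmetic mean of per-model values,
rounded half-up at 4 decimals (the convention that reproduces a
printed four-model average of 0.7533 from 0.7360/0.6700/0.7700/0.8370).

t-SNE diagnostics use PCA initialization and a fixed seed; perplexity
is lowered automatically (with a warning) for small samples.

## Problem sizes in the validation harness

The acceptance checks use: 50 seeded subspace pairs (D ≤ 10, d ≤ 3)
for the GFK oracle; 500 replicates for unbiasedness; 200 null
replicates at m = n = 40 with 500 permutations for calibration; 20
seeded studies (40 HC/site, π = 0.5, off-core 2 SD) for recovery; 10
paired seeds at tuning budget 5 and 2 repeats for the three-experiment
pattern. These sizes give 3-SE Monte-Carlo bands well inside the
asserted margins while keeping a full run in minutes on one CPU.

## Known limitations

* Two sites only; the pairwise GFK construction does not extend
  directly to three or more cohorts.
* Greedy selection is a heuristic: it is monotone and deterministic
  but not optimal, and with the unbiased estimator its terminal MMD²
  is biased downward (see above).
* The quadratic-time MMD estimators are intended for clinical-scale
  cohorts (hundreds of subjects); no linear-time variant is provided.
* The GFK feature space is not interpretable region-by-region; the
  method identifies homogeneous subjects, not discriminating features.
* How many subjects a real study should retain (target size vs
  p-value threshold) is a scientific choice; both rules are provided
  and neither is privileged.
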