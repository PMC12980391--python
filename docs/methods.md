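# Methods

## Study design and the estimand

The design is a randomized three-arm acute-exercise trial (EE = endurance,
RE = resistance, CON = resting control) with blood sampling at pre-exercise,
20/40 min during exercise (EE and CON only — blood cannot be drawn safely
during resistance exercise), and 10 min, 30 min, 3.5 h and 24 h
post-exercise. Participants are randomized to a *temporal profile*
(early / middle / late / all) that determines which of the three later
post-exercise samples exist; everyone contributes pre and post-10-min. This
planned missingness spreads collection burden while covering the full
recovery window, and it is the reason a repeated-measures model that uses
all available observations is preferable to complete-case analyses.

The estimand is the difference-in-changes
Δ²(g, t) = (μ_{g,t} − μ_{g,pre}) − (μ_{CON,t} − μ_{CON,pre}): the exercise
arm's change from baseline net of the change a resting participant shows
over the same clock time (fasting, circadian drift, responses to the
biopsy/collection procedures). Group-specific contrasts
(μ_{g,t} − μ_{g,pre}) are reported for effect-size context only; the RE-vs-EE
comparison is implemented as a difference of within-group changes
(Δ_RE − Δ_EE), with a configuration switch for the direct cell comparison,
since both are defensible algebraic readings of "resistance vs endurance".

## The differential-abundance engine

Per feature: a no-intercept cell-means design (one indicator per observed
group × timepoint cell, so hypotheses are linear contrasts of cell means)
plus covariates — continuous covariates mean-centered to keep cell means
interpretable, categoricals one-hot with the first level dropped. The model
adds a participant random intercept and is fitted by REML. Because the
model has a single variance ratio λ = σ²_u/σ²_e, the REML criterion is
profiled to a one-dimensional problem: after whitening, the marginal
covariance is σ²_e(I + λZZ'), whose eigenvectors do not depend on λ; one
symmetric eigendecomposition per design makes each REML evaluation diagonal
arithmetic. Contrast tests use Satterthwaite degrees of freedom
(df = 2c²/(g'Ag), c = Var(L β̂), g its gradient in (σ²_u, σ²_e), A the
inverse observed REML information, both by central finite differences).
The implementation reproduces lmerTest's t-tests to ~1e-6 on a frozen
fixture and statsmodels MixedLM's variance components to 1e-5 (see the
test suite).

Eligibility: a contrast is tested for a feature only when every group it
involves has ≥ 3 participants observed at both pre and the contrast
timepoint; ineligible pairs are excluded from the model and from the BH
denominator. BH adjustment is step-up within each
contrast|group|tissue|ome|timepoint stratum and never pools across strata;
the stratum string makes the rule auditable in the output table.

For transcript counts the engine computes voom-style precision weights: a
per-gene OLS fit on log2-CPM, a lowess regression (span 0.5) of
sqrt(residual SD) on average log2-count, and per-observation weights equal
to the predicted sqrt-SD at the observation's fitted log-count raised to
the −4th power. Weights require ≥ 10 genes; a degenerate (all-constant)
panel is refused rather than silently unweighted.

Non-convergent REML fits are flagged and reported with NaN p-values in a
failure sidecar; they are never silently dropped or replaced by a z-test.

## The synthetic-data generator

The generator is parameterized exactly by the summaries a repeated-measures
analysis cares about: per sex × group subgroup, a mean vector over
timepoints, a timepoint covariance, and marginal skewness/excess kurtosis.
Margins are Fleishman cubic transforms of standard normals (deterministic
solver: fixed starting points, hybrid root-finder, residual < 1e-10;
infeasible pairs fail with the attainability bound γ₂ ≥ γ₁² − 2).
Dependence is induced by Vale–Maurelli intermediate correlations — the
normal-scale correlation solving a cubic so the transformed margins hit the
target correlation — with a PSD repair (eigenvalue clip at 1e-10) for the
assembled matrix. Missingness is applied structurally from the temporal
profiles, deterministically allocated in uniform quarters (remainder to the
'all' profile); an extra MCAR layer is available but defaults to 0 because
the design's blood missingness is planned rather than accidental.

**Correlation structure.** Preset covariances use *exchangeable*
within-participant correlation (default 0.5). An AR(1) option exists for
sensitivity analyses, but it is not the preset: with AR(1) truth the
random-intercept working model is misspecified and its Satterthwaite test
becomes conservative (~2.8% at the 5% level even with normal margins),
which contradicts the calibrated behaviour the benchmark is designed to
exhibit; a calibrated random-intercept analysis implies a covariance
compatible with exchangeable correlation over the analyzed timepoints.

**Presets.** "adipose" (n = 4 per sex × group subgroup, skew 1.5, excess
kurtosis 6), "muscle" (n = 10, skew 1.0, kurtosis 3), "blood" (n = 30,
skew 0.8, kurtosis 2), all with a 0.5-SD sex baseline shift so the sex
covariate is non-trivial. These are synthetic stand-ins spanning plausible
regimes — subgroups as small as 4, strong non-normality — not estimates of
any real cohort's moments. Consequently the benchmark's rates characterize
the *methods under these conditions*; they are not re-measurements of any
particular dataset.

Count data are negative-binomial via a gamma–Poisson mixture with
dispersion φ(μ) = a + b/μ (decreasing in the mean, the familiar bulk
RNA-seq shape), log-normal library sizes, and an optional multiplicative
batch shift. Multi-platform metabolite fixtures share RefMet ids across
platforms with platform-specific log-normal noise whose CV is the
platform's nominal internal-standard CV, left-censor below a quantile
(MNAR) and add MCAR; the truth record stores which platform should win
redundancy resolution.

## The model-selection benchmark

Six strategies reduce each simulated feature dataset to one p-value for the
same difference-in-changes hypothesis. Scenario: EE + CON arms, 2 sexes,
5 timepoints (pre, post 10/30 min, 3.5 h, 24 h), profile missingness,
contrast at post-10-min (the first timepoint shared by all arms); the
alternative adds δ (default 1 marginal SD) to the EE mean at that
timepoint. The realized design is fixed within a run — matching how a
simulation aligned to an observed study reuses that study's design — so
rates are conditional on the design and their Monte-Carlo SE is the
binomial formula.

Implementation notes per strategy:

* **paired_t** — pooled two-sample t on per-participant (post − pre)
  change scores, exercise vs control; the only pairwise-t variant that
  tests the delta-delta null.
* **ols** — cell-means regression treating observations as independent.
  For a within-participant contrast this *over*-estimates the SE, so OLS
  is conservative/low-power here rather than anticonservative.
* **lmm_ri / lmm_ri_weighted** — the differential engine; weights only
  apply to count-mode data, so the two coincide on continuous scenarios.
  Vectorized across replicates by sharing the design eigendecomposition;
  λ is profiled on a 62-point log grid with parabolic refinement, and the
  batched path agrees with the per-feature path (tested).
* **mmrm_unstructured** — multivariate-normal fit with unstructured T × T
  covariance by EM over missingness patterns, including the REML-type
  M-step correction (each cluster contributes X_c Cov(β̂) X_c' on its
  observed block) so Σ̂ is not deflated by the estimated means; Wald t
  with a cluster-level df (participants − number of groups), a
  deliberately conservative reference since 15 covariance parameters are
  estimated from as few as 16 clusters. EM runs at most 100 iterations
  (relative tolerance 1e-5); non-converged replicates are flagged and
  counted, never resampled.
* **gee_ar1** — working AR(1) correlation over timepoint index with a
  moment estimator of ρ from lag-1 residual products, robust sandwich
  covariance and a Wald z test *without* small-sample correction. The
  resulting inflation at few clusters is the point of including it; the
  independence limit reproduces statsmodels GEE exactly (tested).

At 20,000 null replicates on the adipose preset the weighted LMM rejects at
≈ 4.5–5.0% (slightly conservative, as Satterthwaite tests tend to be with
skewed data and tiny subgroups) and GEE at ≈ 8.2–8.8%; under the δ = 1
alternative the power ordering is GEE > weighted LMM ≥ paired t ≈ MMRM >
OLS. These numbers are recomputed, not stored: `scripts/acceptance.py` and
the acceptance tests run the full simulation each time.

Replicate counts are configurable (default 20,000, with the MC SE always
reported); the benchmark reports bands rather than digit-level matches
because the rates depend on the generating moments.

## Preprocessing chains

Metabolomics, per platform, in fixed order: average duplicate-id rows
(NaN-ignoring mean) → non-positive values to missing → drop features with
> 20% missing (strict) → impute (feature-profile KNN for panels of > 12
features; half-minimum for ≤ 12 — 12 itself is unspecified upstream and
takes the conservative small-panel branch) → log2(x+1) → median-MAD
normalization for untargeted assays, gated on four Kruskal–Wallis tests
(sample medians and upper quartiles vs sex and sex × group; any p < 0.01
skips normalization, because location statistics that track biology must
not be removed). KNN imputation uses Euclidean distance on shared observed
samples rescaled by overlap, requires ≥ 3 shared samples per neighbor pair,
k = 10, 1/distance weights, and copies exact-duplicate donors verbatim.
PC outlier flags: box-plot whiskers at m × IQR on the leading PC scores
(metabolomics m = 5 on 5 PCs — the PC count is unstated upstream and
configurable; proteomics m = 3 on 3 PCs). Redundancy across platforms:
per-platform CV = mean over internal standards of sd/mean on the raw
intensity scale; each shared RefMet id keeps the lowest-CV platform's
measurement, with losing platforms recorded. The Kruskal–Wallis gate is
applied per platform (before merging), since normalization is a
per-assay decision.

RNA-seq: RIN < 5 samples excluded (missing RIN excluded with a warning);
low-expression filtering defaults to the edgeR-style reading (keep genes
with CPM > 0.5 in ≥ 10% of samples) with the literal removal rule
available as `mode="literal"` — the literal sentence describes removed
genes as those low "in at least 10%" of samples, which would remove nearly
everything, so the intended rule is the default and both are logged. TMM
factors follow the standard construction (75th-percentile reference, 30%/5%
double trim, inverse asymptotic binomial variance weights, geometric mean
1) and reproduce edgeR::calcNormFactors to 1e-6 on a frozen toy. Log-CPM
uses prior count 0.5 (a common default; the upstream description is
silent). Batch regression fits the protected design (age, sex,
group × timepoint cells) jointly with batch columns and subtracts only the
batch component; batch variables confounded with the protected design
(e.g. extraction batch perfectly collinear with exercise modality) are
refused, leaving the limitation documented rather than absorbing biology
into a batch term.

## Enrichment, clustering, CCA

Z-score matrices take z = estimate/SE when the SE exists (avoiding p-value
underflow; backtransformed p's are clipped at 1e-300 otherwise), keep the
most extreme z per gene × contrast (ties by feature-id order), and drop
unmapped features with a logged count. Sets are intersected with the
measured universe and kept when ≥ 5 members survive and ≥ 70% of the
original set is retained (both boundaries inclusive). The competitive test
compares in-set vs out-of-set mean z with the in-set variance inflated by
VIF = 1 + (m−1)ρ, ρ = 0.01 by default (the method's established default),
t reference with G − 2 df; ρ = 0 reduces exactly to the two-sample t. ORA
is the upper-tail hypergeometric. Both are BH-adjusted within
tissue × ome × contrast × collection.

Temporal clustering operates on group-wise per-timepoint mean profiles
(matching one-curve-per-feature trajectory displays; subject-level
clustering is out of scope), z-scored along time, fitted per exercise mode.
Fuzzy c-means uses Bezdek's alternating updates with k-means++-style
seeded initialization; the fuzzifier defaults to the Schwämmle–Jensen
estimate from (feature count, dimension) with fallback m = 2. The
objective is asserted non-increasing every run. The cluster number is the
elbow of the minimum-centroid-distance curve: the curve kinks (maximum
positive second difference) at the first over-split c, and the elbow is
the c just before it; a manual override mirrors visual inspection.

Sparse CCA is the penalized matrix decomposition: alternating
soft-thresholded power iterations on X'Z with L1 budgets enforced by
bisection, deterministic start (column-sum direction), sign convention
anchored on the largest trait weight. Penalties are tuned by the
permutation z-statistic (Fisher-z of the real correlation standardized
against ≥ 50 row-permutations; grid points with zero permutation SD are
skipped). Successive variates deflate the cross-product by the PMD
projection (not residualization — the convention of the reference
implementation). Traits are standardized globally (not per sex) and
missing trait values are mean-imputed with a log message. The no-sparsity
limit equals the leading singular pair of X'Z (tested), and on planted
sparse structure the tuned support covers the true support when individual
loadings are weak enough that truncation costs real correlation.

## Numerical choices and degenerate inputs

* REML λ is searched in log-space on [−12, 12] with the λ = 0 boundary
  checked explicitly; at the boundary, Satterthwaite falls back to the
  residual df when the information matrix is singular.
* Design rank deficiency names the aliased columns; empty design cells are
  dropped with a warning, and contrasts touching them are skipped and
  recorded rather than failing the whole ome.
* FCM features coinciding with a centroid get crisp membership 1; zero-MAD
  samples, all-missing features, zero cross-products, and whole-universe
  sets all raise with named offenders.
* BH propagates NaN p-values and excludes them from the stratum's m.

## Problem sizes

Defaults were chosen so the full test suite runs in a few minutes and the
acceptance computation in well under a minute on one CPU: 20,000 benchmark
replicates per scenario (MC SE ≈ 0.15% at a 5% rate), 10⁵-draw moment
checks, 10⁶-draw Fleishman oracles, planted-recovery datasets of 40–400
features. All are configurable upward.

## Known limitations

* The preset moments are stand-ins; absolute rates transfer to real data
  only insofar as real covariances resemble the exchangeable preset.
* The mode-vs-mode contrast algebra and several upstream ambiguities
  (KNN details, PC count, literal vs intended expression filter, z-score
  source) are resolved by documented defaults with switches, not by
  claiming the upstream choice is known.
* MMRM uses a cluster-level df rather than Satterthwaite/Kenward–Roger;
  its absolute power is therefore conservative by construction.
* GEE's default is the uncorrected sandwich, deliberately, as the
  benchmark's purpose is to exhibit the small-sample inflation; the
  Mancl–DeRouen bias correction is available (`bias_corrected=True`) and
  pulls the null rate back near nominal, but it is not a benchmark
  strategy.
* No empirical-Bayes moderation across features: each feature is fitted
  independently.
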