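# Methods

`gmsubtype` discovers atrophy-based disease subtypes in a cohort of
dementia patients from a subjects × ROI table of gray-matter (GM)
volumes, then characterizes the subtypes cross-sectionally and
longitudinally.  This note documents the models, the parameters that
matter, the synthetic cohort the test-suite runs on, and the design
choices made where the method family leaves them open.

## The clustering model

**Input.** One row per subject with 96 atlas-defined GM volumes (82
cortical, 12 subcortical, 2 brainstem, in mm³), center of origin,
intracranial volume (ICV), age, and clinical covariates.

**Preprocessing.** Each ROI is residualized by ordinary least squares
on center of origin (indicator-coded) and ICV (continuous, fit on the
full analyzed sample).  Continuous covariates are standardized
internally for conditioning and coefficients back-transformed; the
residuals are identical either way.  Constant covariates (a
single-level center, constant ICV) are dropped, so the model
degrades gracefully to mean-centering; genuinely collinear designs
raise a rank-deficiency error.

**Random-forest proximity.** A two-class random forest discriminates
the observed subjects from an equal-sized synthetic contrast sample in
which every feature column is independently permuted — this keeps each
ROI's marginal distribution but destroys the between-ROI dependence,
so the forest's splits track the joint structure of the real data.
The proximity of two observed subjects is the fraction of trees in
which they share a terminal node.  Defaults: 2000 trees per forest,
`sqrt(p)` candidate features per split, and the proximity averaged
over 5 forests with independent contrast draws to damp Monte-Carlo
noise (one forest's proximities have entrywise sampling SD up to
~`0.5/sqrt(n_trees)`).  All of this is seeded and configurable.

**Dissimilarity and tree.** `d = sqrt(1 − proximity)` (the transform
that makes proximities behave like squared distances; the plain
`1 − proximity` is available via `transform="linear"`), then
unweighted group-average (UPGMA-style) agglomeration.  Merge heights
were verified against a brute-force O(n³) agglomerator on 1000 random
instances.

**Model selection.** The tree is cut at each K in 2..10 and the
Calinski-Harabasz index — between-cluster dispersion per df over
within-cluster dispersion per df — is evaluated *in the residual ROI
feature space* (CH is defined on feature-space dispersions; computing
it on the dissimilarity would measure a different quantity).  The
chosen K maximizes CH, lowest K winning ties; a cut with zero
within-cluster dispersion reports CH = +inf with a degenerate flag.
The dendrogram is exported (Newick) for visual inspection, but the
selection rule itself is strictly argmax CH.

**ROI importance and discrimination.** A supervised forest predicting
the final cluster labels from all 96 residuals yields the mean
decrease in Gini impurity per ROI; "contribution to the clustering"
is read as discriminating the clusters (an unsupervised-forest
variant was considered and rejected because the real-vs-synthetic
importances rank dependence, not cluster separation).  The top-10
ROIs are refit in a reduced forest whose out-of-bag confusion matrix
measures discrimination; for each ROI, the clusters are split at the
largest gap in their sorted means to report *which* groups the ROI
separates.  Forest fits sort rows into a canonical (lexicographic)
order first, so importance rankings do not depend on subject order.

**Stability.** The proximity construction is repeated `n_repeats`
(default 100) times with seeds `base_seed + r`; each repeat reports
the mean (and max) absolute elementwise difference from the main
matrix over the upper triangle.  Identical seeds reproduce the matrix
exactly.  Note that the *absolute* mean difference scales with the
overall proximity level, so comparisons across datasets should use
the difference relative to the mean proximity.

## Cross-sectional characterization

- **Group battery**: one-way ANOVA for continuous variables (raw
  values or exact reconstruction from per-group mean/SD/n), Pearson
  chi-squared without continuity correction for categorical ones,
  available-case per variable.  Post-hoc: pairwise Welch t-tests with
  Bonferroni correction over the three pairs (the post-hoc procedure
  is not pinned down by the method family; the choice is recorded in
  the output metadata).  Baseline MMSE additionally gets an ANCOVA
  adjusting for age and education, and WMH an ANCOVA adjusting for
  age.
- **Per-ROI ANCOVA**: volume ~ cluster + age per ROI (on center/ICV
  residuals by default, raw volumes optionally), F test of the
  cluster factor, Benjamini-Hochberg FDR across the 96 ROIs at
  α = 0.05.
- **z-profiles**: residualize on ICV, center and age (pooled), then
  per cluster and ROI `z = (cluster mean − reference mean) /
  reference SD`.  The reference cluster's own SD is the default
  denominator (the reference is treated as the normative group);
  whole-sample SD is available via `sd_mode="pooled"`.  The atrophy
  mask uses a strict `z < −0.5`.  Because the adjustment is pooled,
  any cluster difference that is collinear with age or center is
  partially absorbed — by design, the same thing happens in the
  age-adjusted analyses of real cohorts.
- **Basal-ganglia/cortical ratio**: Σ(6 BG volumes)/Σ(82 cortical
  volumes) per subject, computed on raw volumes (the ratio is scale
  invariant, so ICV adjustment is unnecessary); cluster comparisons
  use Welch 95% CIs.

## Longitudinal model

MMSE at months 0/12/24/36 is modelled as
`mmse ~ cluster * visit (+ WMH)` with a random intercept per subject,
fit by REML (statsmodels `MixedLM`).  Visit is categorical — the
deliverable is per-visit estimated marginal means, not a slope — with
a continuous-time variant straightforward to add on the long-format
table.  EMMs are model cell means with covariates at their sample
means; SEs come from the fixed-effect covariance.  Contrasts use the
normal (Wald) approximation rather than Satterthwaite degrees of
freedom, which is mildly anticonservative in small cells; with ~150+
subjects the simulated coverage of 95% intervals is 92–98%.
Non-convergence raises; a boundary variance component warns but the
fit is retained.

## The synthetic cohort

No subject-level data are distributable for this kind of multicenter
clinical cohort, so the package ships a generator
(`SimulationSpec` / `simulate_cohort`) whose defaults emulate the
cohort the pipeline is designed for: 165 patients in three latent
subtypes of 49/76/40 across four centers.

ROI volumes follow a log-normal multiplicative model:

    log V_ij = log B_j + log(ICV_i/ICV0) + center_i + β_age·(age_i−70)·[cortical]
               + noise_sd·(class + lobe + ROI effect)_{c(i),j} + noise_sd·ε_ij

with per-ROI baselines `B_j` chosen at plausible adult magnitudes
(bilateral cortical total ≈ 452 cm³, basal ganglia sized for a
baseline BG/cortical ratio ≈ 0.032).

Calibrated defaults (one-time choices, not free dials):

- **Cluster sizes, age, education, sex, MMSE, WMH, clinical
  frequencies, center allocation** are set to the cohort-table
  marginals of the target study population (e.g. ages 73.43/69.05/
  63.68 ± ~8; baseline MMSE 21.57/22.93/24.50).  MMSE latent means
  are compensated for the [0, 30] clipping so the *observed* baseline
  means hit their targets (verified to <1% at n = 10,000/cluster).
  Center allocation uses fixed largest-remainder quotas per cluster
  (a study's center-by-cluster table is a fixed observed table); the
  default cohort reproduces its target table exactly, including its
  chi-squared of 27.800.
- **Atrophy patterns**: cluster 1 loses ~18% of cortical volume
  uniformly ("cortical predominant"); cluster 2's deficit is
  concentrated in frontal+occipital lobes (~17% there, ~1.5%
  elsewhere; "fronto-occipital"); cluster 3 is spared ("subcortical
  predominant" only in the relative sense).  These average log-shifts
  (−0.18 / −0.104) are pinned by the target BG/cortical ratio means
  of ≈0.037/0.034/0.031; the generated cohorts land within ~3% of
  them.  Basal ganglia volumes are equal across clusters, so the
  ratio differences arise purely from the cortical denominator — the
  structure the ratio is designed to detect.
- **noise_sd = 0.045** (≈4.5% residual volume CV) is the one
  parameter no marginal pins down.  It was chosen once so that the CH
  landscape of default cohorts matches the regime the method is
  reported to operate in (CH peaking at K=3 in the ~120–160 range,
  clearly above K=2 and K=4) and fixed thereafter.
- **Age effect −0.1%/yr on cortical log-volume.**  An age slope acts
  as a *shared* within-cluster factor across all 82 cortical ROIs and
  is nearly collinear with the cluster-1 direction; at −0.5%/yr the
  within-cluster cortical residual correlation reaches ~0.7 and no
  clustering method (including a Ward/k-means oracle) recovers the
  planted partition at n=165 with the table-calibrated age SDs.
  −0.1%/yr keeps age confounding present (10-year age gap ≈ 1%
  volume) while leaving the planted structure recoverable; the
  age-adjustment machinery is additionally exercised by tests that
  plant much larger age effects in their own specs.
- **MMSE trajectories**: annual slopes −2.5/−1.5/−0.5 points/yr
  (subtype-divergent decline), subject-level intercept SD set so the
  observed baseline SD matches its target, visit noise SD 1.5,
  missing-completely-at-random visit retention 0.994/0.588/0.461/
  0.182 matching the per-visit available n of the target cohort.
- **Optional exchangeable within-subject noise correlation**
  (`roi_correlation`, default 0): real morphometry has shared
  variance (global atrophy severity); the default cohort omits it
  because the within-cluster covariance of the emulated study is
  unknown, and planting it materially changes what the proximity
  forest keys on.

**What passing on synthetic cohorts does and does not show.**  The
generator plants independent (or exchangeably correlated) log-normal
noise, linear covariate effects, and MCAR dropout.  Real cohorts have
spatially structured covariance, site-by-sequence effects beyond a
multiplicative offset, informative dropout, and measurement error in
segmentation.  Green tests demonstrate that the pipeline recovers the
structure it claims to recover under its stated model, with correct
error control — not that any particular real dataset contains three
subtypes.

## Numerical choices

- Ties everywhere break toward the lowest index (stable sorts;
  lowest K on CH ties).
- All randomness flows from explicit integer seeds; the pipeline
  expands one global seed into per-stage seeds via
  `numpy.random.SeedSequence` and logs them in the run manifest.
- Floats serialize at 17 significant digits and are re-read with
  round-trip parsing, so exported artifacts are bit-faithful.
- Chi-squared requires integer counts and non-degenerate margins;
  FDR validates p ∈ [0, 1]; the ratio errors on a non-positive
  cortical sum; ANCOVA records per-ROI errors (missing data, rank
  deficiency) as row entries instead of aborting the table.

## Known limitations

- The proximity forest's resolution degrades for clusters whose
  pattern is a strict "middle" interpolation of two others; such a
  cluster has no region where real density exceeds the permuted
  contrast and its within-cluster proximity falls below its
  between-cluster proximity.  Directionally distinct patterns are
  required for recovery — a property of the method, not of this
  implementation.
- Center residualization with cluster-imbalanced centers absorbs part
  of the cluster signal into the center coefficients (the center
  dummies are confounded with cluster composition).  With strongly
  imbalanced small centers this can displace a center's members
  toward another cluster.
- Wald contrasts (no Satterthwaite df) and random-intercept-only
  trajectories; random slopes are not planted by the generator and
  not fit by default.
- No site-harmonization beyond linear center effects, no nonlinear
  covariate adjustment, no imputation of missing MMSE.
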