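# Methods

This note documents the models and procedures implemented in `survbench`,
the assumptions behind them, the parameters that matter, and the numerical
and design choices made where the design was genuinely open.

## Exact concordance index

The concordance index is computed by exhaustive enumeration of all
unordered sample pairs rather than pair sampling, making it deterministic.
Conventions (Harrell-style):

- **Comparability.** A pair is comparable iff the observed times differ and
  the earlier sample had the event. Under right censoring any other pair's
  true ordering is unknown. Pairs with *tied event times* are excluded: the
  convention for such pairs is not universal, and excluding them is the
  dominant choice; the bookkeeping (`n_comparable_pairs`, `n_concordant`)
  makes the policy auditable.
- **Prediction ties** earn half credit. Counts are accumulated in integer
  half-credit units and divided once at the end, so results are bit-stable
  across platforms.
- **Degenerate input.** A dataset with no comparable pair raises an
  explicit error; it is never silently scored 0.5.
- **Model comparison** uses 100 bootstrap resamples of the scored roster;
  both models are scored on each resample and the paired per-replicate
  differences enter a two-sided Wilcoxon signed-rank test. Resamples with no
  comparable pair are redrawn and logged; identical models short-circuit to
  p = 1 (the signed-rank statistic is undefined on all-zero differences).

## Feature engineering

**Segment-to-gene summarization.** Gene-level copy number is the
*unweighted* mean of the segmented log-ratios of all segments overlapping
the gene interval; any shared base counts as overlap, and all coordinates
are 1-based inclusive. Genes overlapping no segment are missing (NaN) and
are imputed with the training-split mean only at design-matrix time.

**Probe-to-gene summarization.** One probe passes through; two probes
average; for more than two probes the probe-by-sample block is row-centered
and decomposed by SVD, each probe is weighted by the fraction of its
variance explained by the first eigengene, and the gene value is the
weighted mean of the raw probe rows. A zero-variance block falls back to
the unweighted mean (logged).

**GII.** The genomic instability index is the fraction of non-missing loci
with log2 ratio above `tau_amp` or below `tau_del`. Defaults are ±0.3 —
symmetric and conventional for single-copy changes on segmented array data —
and configurable (`GiiThresholds`). Missing loci are excluded from both
numerator and denominator; an all-missing sample is an error.

**Univariate Cox screening.** Selection strategies screen thousands of
features with single-covariate Cox fits, so the Newton iteration on the
Breslow partial likelihood is implemented vectorized across features
(standardized internally; coefficients reported on the original scale; Wald
p-values from the observed information). The test suite checks it against
`lifelines` on random censored data. Monotone-likelihood fits (the MLE
diverges) are capped and reported as non-converged with NaN coefficients;
in batch screening such features, and constant or missing-valued features,
contribute p = 1 so they rank as uninformative rather than crashing a scan.

**MASP.** Each of `n_repeats = 100` repeats draws `chunk_size = 50`
training samples *without replacement, fresh per repeat* (100 × 50 exceeds
the training set, so the chunks cannot be a partition), scores every gene by
univariate Cox, and the evidence is aggregated as `S_i = Σ_j −log10 p_ij` —
monotone in evidence, Fisher-style; the per-repeat p-value table is
returned so any other aggregate can be formed. Genes are sorted by `S_i`
descending (ties broken by gene id) and the sorted list is walked keeping
genes in the prior list until `k = 50` are kept — filtering *after* global
sorting, not before scoring. Chunks with fewer than 2 events are redrawn
and logged.

**Selection discipline.** Every strategy is fitted on the training split
only and frozen (`FittedCategory`), including the imputation, centering and
scaling statistics; transforming a cohort never re-selects. Property tests
perturb validation samples and assert selections do not move.

## The controlled grid

The default design crosses 15 feature categories with 4 learners. The
categories: six molecular pre-selection strategies (top-1000 by marginal
Cox association, top-1000 by variance, a cancer-census-style list in full, a
Higgins-style top-1000-by-variance within an oncogene list, a
clustering-gene list in full, and MASP), the same six plus all clinical
covariates, clinical covariates alone, clinical + GII, and clinical + GII +
MASP. GII is never used alone (it is a single feature). Clinical encoding:
age/size/grade numeric (standardized on training statistics), binary
markers and treatments 0/1, histology dummy-coded against the lobular
baseline. The full roster is 16 covariates; category assembly accepts a
configurable subset since published variants of this covariate set differ
by a few derived flags.

**Learners.** The algorithms are deliberately off-the-shelf
(scikit-survival): penalized Cox via the elastic-net path (lasso
`l1_ratio = 1`, elastic net `0.5`), gradient-boosted Cox (100 trees, depth
3, learning rate 0.1) and random survival forest (100 trees,
`min_samples_leaf = 10`, sqrt features) — the deliverable is the contract
around them. All emit risk scores, negated to the package-wide convention
*higher = longer predicted survival*; sign bugs surface as grids scoring
systematically below 0.5, which the tests check. Penalties are chosen by
seeded 3-fold cross-validation of the exact c-index along the coxnet alpha
path; if the chosen alpha fails numerically the fit falls back to the next
heavier penalty (logged) rather than failing the cell. With
`penalize_clinical=False`, clinical and aggregate columns get zero penalty
factor so they are always retained (glmnet rescales penalty factors to sum
to the feature count, so the all-unpenalized case instead drives the global
penalty to ~0). `rank_transform=True` replaces each feature by its
within-training average rank, with validation values mapped through
interpolated training quantiles (the mapping at unseen values is a design
choice; exact rank invariance is guaranteed on training values).

**Ensembles.** Members are converted to within-roster ranks on the scored
(validation) roster — ascending, average ranks on ties — and averaged per
sample. The default grid yields one ensemble per category, one per learner
and one grand ensemble (15 + 4 + 1 = 20). Because the direction convention
is fixed, ranking by predicted survival vs by risk differs only by
reflection and does not change ensemble c-indices. In `run_grid`, a failed
cell is recorded as a failed leaderboard row and excluded from its
ensembles' membership (membership is recorded in provenance); an ensemble
row fails only if its whole group failed.

**Controls.** The negative control permutes (time, event) jointly across
samples, separately within training and validation, and reruns the grid;
the permutation is guarded against the identity. The positive control
predicts ER status from each category's molecular features with the
classification analogue of each learner (gradient-boosting /
random-forest / penalized-logistic classifiers), scoring predicted
probabilities against the binary label with the same exact concordance
routine (equal to AUC); the designated ER expression measurement is removed
*before* selection and its absence from every design is asserted. The
random-feature null refits the learner on all clinical covariates plus
fresh random draws of 50 molecular features and reports the add-one
empirical p-value `(1 + #{null ≥ candidate}) / (n + 1)` — never zero.
Cross-cohort consistency re-scores frozen cells (frozen selection + frozen
fit) on an independent cohort sharing the feature namespace and reports the
Pearson correlation of the model-score vectors. A balanced two-way ANOVA of
grid scores on category and learner is provided as a descriptive
convenience only.

## Synthetic cohort generator

The generator's defaults are the study conditions: 980 samples split
500/480-style, subtype mix 55% luminal / 25% basal / 20% HER2-enriched,
receptor positivity conditional on subtype (ER+ in 92% of luminal, 10% of
basal, 25% of HER2-enriched; HER2+ in 95% of the HER2-enriched subtype),
grade skewed high in basal/HER2 tumors, and a clinical roster (age, tumor
size, nodes, grade, ER/PR/HER2, three treatments, five histologies, two
derived flags) with dependencies a clinician would expect (hormone therapy
follows ER status; chemotherapy follows grade, nodes and youth).

- **Copy number.** A per-sample instability latent `z = 0.9·HER2 +
  0.35·(grade − 2) + 0.3·basal + N(0, 0.5)` sets the per-run aberration
  probability (logistic in `z`, range ≈ 0.03–0.48). Segments are
  alternating normal/aberrant runs over a fixed locus grid (5 chromosomes ×
  40 one-megabase loci by default; mean run 8 loci), aberrant log-ratios
  `N(±0.6, 0.2)`, normal `N(0, 0.05)` — well separated from the ±0.3 GII
  thresholds so threshold behaviour is unambiguous. Gene-level values are
  produced by the package's own segment-to-gene summarizer, so the
  generator and the features module cannot drift apart.
- **Expression.** Unit-variance noise plus: subtype centroid shifts on 150
  genes (`N(0, 0.8)` per gene and subtype), an ER program of 30 genes
  shifted by 1.2 in ER-positive samples (the first is the designated "ER
  measurement", shifted further), and a planted 20-gene prognostic module
  loading 0.9 on a latent factor with residual sd 0.6.
- **Survival.** Weibull times (default shape 1 = exponential) with hazard
  `∝ exp(β_clin·x + β_GII·z_GII + β_genes·z_module)`. Default log-hazard
  effects follow the usual directions for breast-cancer overall survival
  (age 0.45, size 0.25, nodes 0.40, grade 0.20, PR −0.25, hormone −0.30,
  radiation −0.15, HER2 0.20, chemo 0.10, ER −0.10 on
  standardized/indicator scales), GII 0.5 on the standardized realized
  aberration fraction, and 0.8 on the standardized planted-module mean —
  the module weight is set so the module is *recoverable*: it must dominate
  the incidental survival association that subtype- and ER-driven genes
  inherit through their clinical correlates, which is the planted-structure
  contract the selection tests rely on. Censoring is the minimum of an
  exponential time — whose rate is solved by bisection on the drawn sample
  so the realized censored fraction hits the target (default 0.55) — and a
  180-month administrative horizon.
- **Prior gene lists.** Synthetic stand-ins for curated resources
  (oncogene/TF 200, census-style 487, clustering 150, 70-gene centroid,
  21-gene weighted with signed weights, planted genes weighted toward
  risk); each embeds the planted module plus seed-dependent decoys; default
  sizes clamp to half the gene universe on small cohorts. All randomness
  flows from one seed through named `SeedSequence` child streams, so equal
  configs give bit-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level noise, batch and platform effects,
missing clinical values, non-proportional hazards, informative censoring,
subtype-specific censoring, and the cross-platform normalization issues of
multi-cohort studies. Cross-cohort consistency runs here share a generator
and thus overstate the consistency achievable across truly independent
platforms.

## Signatures

The weighted score z-scores each signature gene (training statistics when a
split is given — published practice is ambiguous about the normalization
cohort, so the training-statistics convention is fixed and documented),
takes the weighted sum, and negates it (the weighted sum measures risk).
The centroid score standardizes the signature genes, averages the profiles
of samples *observed* to survive past the horizon (patients censored before
the horizon are excluded from the reference — their survival past it is
unknown), and scores each sample by Pearson correlation to that profile.
Zero-variance genes are dropped from both; z-scoring makes both scores
invariant to per-gene affine rescaling of the raw expression.

## File formats

Cohorts are directories of TSVs (expression, gene-level CN, clinical,
outcome, split, gene annotation), a SEG-style segments table, JSON gene
lists and planted truth, and a YAML generator config. Floats are re-read
with round-trip parsing so write→read is bit-identical. Leaderboards
serialize to CSV or JSON sorted by c-index descending with lexicographic
model-id tie-breaks; duplicate model ids are rejected.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to keep
every planted effect detectable: cohorts of 120–980 samples and 240–600
genes, full 15 × 4 grids at 240 samples, the random-feature null at 25
models (configurable to 100), MASP properties at the default 500-sample
training scale, and multi-seed properties over 5–10 seeds. The null
calibration of the c-index uses 500 replicates at n = 500.

## Known limitations

- Cox-family and boosting adapters assume proportional hazards; the exact
  c-index itself does not weight by the censoring distribution (no inverse
  probability of censoring weighting; no time-dependent AUC, by design).
- The Newton screener uses Breslow tie handling; with heavily tied times
  its p-values drift slightly from Efron-based fits.
- The positive control's classifier analogues are fixed mappings, not
  tuned equivalents of the survival learners.
- Empirical p-values from small nulls are coarse (minimum `1/(n+1)`).
- The ANOVA convenience assumes a complete balanced grid and no
  category × learner interaction.
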