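# Methods note

This document records the statistical model behind `krassubtype`, the
assumptions baked into each stage, every user-facing parameter with its
default and rationale, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions used throughout.

## 1. Scientific setting

KRAS-mutant lung adenocarcinoma is transcriptionally heterogeneous. Three
expression subtypes with distinct co-mutation biology are recognised:

* **KL** — STK11/LKB1 co-mutated, immunologically "cold";
* **KP** — TP53 co-mutated, inflamed;
* **K** — CDKN2A/B-inactivated, NKX2-1-low.

The package classifies bulk RNA-seq samples into these subtypes from a
384-gene panel and then asks whether the treatment effect in a two-arm trial
(CDK4/6 inhibition with abemaciclib versus erlotinib control) differs by
subtype. Because the underlying patient-level trial data are restricted, the
package ships a generator that produces synthetic cohorts with the same
statistical structure (cell sizes, response proportions, survival medians,
censoring), so every stage is testable end to end.

## 2. Preprocessing

Order of operations (`preprocess_counts`):

1. **Low-expression filter** — a gene is removed when its raw count is below
   `min_count = 5` in at least `sample_fraction = 80%` of samples. Rationale:
   genes with near-zero counts in most of the cohort carry no rank
   information after normalization and destabilise gene-wise standardization.
2. **log2(count + 1)** transform.
3. **Quantile normalization** — every sample is mapped onto the vector of
   mean order statistics across samples. Ties within a sample receive the
   mean of the quantile means their run spans (the standard limma
   `normalizeQuantiles` tie convention). Implemented in-house because the
   installed Python stack has no canonical implementation; correctness is
   pinned by hand-computed oracles and a property test that all columns share
   one sorted vector to 1e-12.
4. **PCA outlier detection** — samples are projected onto the first two
   principal components of the centered sample×gene matrix; a sample is
   flagged when its robust z-score (median / 1.4826·MAD) on either component
   exceeds `outlier_threshold = 6`. Flagged samples are dropped and recorded
   in the `QCReport`.

**Interaction caveat (deliberate):** quantile normalization is invariant to
any monotone per-sample transform, so a *pure global-shift* outlier becomes
indistinguishable after step 3. The detector therefore earns its keep on
outliers that distort the shape of the expression distribution, not its
location. The test suite validates the detector directly on the log2 scale
(where planted shift outliers are found exactly), and the default pipeline
fixtures use `n_outliers = 0`.

## 3. Nearest-centroid single-sample predictor (SSP)

Each sample is correlated (Pearson) with the KL/KP/K centroid profiles over
the intersection of panel genes.

* **Gene standardization** (`standardize_genes = True`): cohort gene-wise
  mean/sd are applied identically to the sample matrix *and* the centroids,
  so correlations are computed in one standardized space. Without this,
  high-variance genes dominate the correlation.
* **Decision rule**: a sample is assigned the argmax-correlation subtype iff
  the maximum correlation ≥ `correlation_threshold = 0.15`; otherwise it is
  *unclassified*. The margin `delta = r(1st) − r(2nd)` is reported. Exact
  ties are broken by subtype order (KL, KP, K) and flagged.
* **Permutation null** (`n_permutations = 1000`): each gene row is
  independently permuted across samples, the per-sample maximum correlation
  is recomputed, and all null maxima are pooled. The empirical p-value uses
  add-one smoothing, p = (1 + #{null ≥ observed}) / (1 + N). This answers
  "how often does a correlation this strong arise with the gene-sample
  linkage destroyed?".
* `min_gene_overlap_fraction = 0.5`: classification refuses to proceed when
  fewer than half of the panel genes survive preprocessing, since the
  centroid geometry is no longer the one the threshold was chosen for.

## 4. Balanced-bootstrap random-forest rescue

Samples the SSP leaves unclassified are rescued by a random forest trained on
a labeled reference set:

* **Per-tree balanced bootstrap**: for each of `n_trees = 500` trees, every
  class is resampled *with replacement* down to the minority-class size, so
  each tree sees an exactly class-balanced bootstrap. This is the point of
  the method (class imbalance in the reference would otherwise bias votes),
  so it is implemented in-house on top of sklearn `DecisionTreeClassifier`
  (`max_features = "sqrt"`, unlimited depth). Bootstrap index sets are
  recorded on the fitted object for auditability.
* **Validation**: the reference is split 3:1 (stratified,
  `train_fraction = 0.75`); one-vs-rest sensitivity/specificity and balanced
  accuracy (mean sensitivity) are reported from the held-out quarter.
* **Provenance**: rescued calls carry `method = "RF"`; SSP calls are never
  overwritten.

## 5. Efficacy analyses

* **Response**: ORR = PR+CR, DCR = PR+CR+SD, over all assigned patients
  (NE counts in the denominator). Arm contrasts via Pearson chi-square
  without continuity correction (`scipy.stats.chi2_contingency`) and via a
  stratified logistic likelihood-ratio test (statsmodels `Logit`, full vs
  reduced model, χ²(1)).
* **Kaplan-Meier**: product-limit estimator computed in-house from a
  vectorized event table; cross-checked in tests against lifelines
  `KaplanMeierFitter`. Median CI by **Brookmeyer-Crowley test inversion** on
  the log(−log S) scale with Greenwood variance, χ²(1) 0.95 cutoff,
  evaluated at event times; the upper bound is reported as *not reached*
  (`None`) when the acceptance region extends to the last event. The
  `identity` transform is also exposed. Built in-house because lifelines
  exposes only the survival-band median CI, not test inversion.
* **Log-rank**: lifelines `logrank_test`.
* **Cox**: lifelines `CoxPHFitter` with Efron tie handling (default) and
  stratification; Breslow ties route through statsmodels `PHReg`.
  Categorical covariates are dummy-encoded (drop-first); interactions are
  products of design columns. Adjusted subtype analyses stratify on sex,
  ECOG PS, prior chemotherapy and KRAS G12C status and adjust for age,
  prior immunotherapy and smoking.
* **Subgroup forest table**: per-level unadjusted HRs; a level with fewer
  than `min_subgroup_events = 5` events is reported *not evaluable* rather
  than fitted.
* **Rank-sum**: `scipy.stats.mannwhitneyu` (`method="auto"`, exact for small
  samples).

## 6. Synthetic-cohort generator

### What it emulates

* **Cell sizes**: KL 24/23, KP 40/30, K 15/16 (treated/control; 148 total).
* **Response**: per-cell multinomial over {CR, PR, SD, PD, NE} with the
  published per-cell counts as probabilities (e.g. KL-treated DCR 91.7%).
* **Survival**: exponential event times with rate ln2/median per
  subtype×arm×endpoint, medians set to the published values (e.g.
  KL-treated OS 13.05 months). Censoring is uniform administrative
  censoring U(0, c), with c calibrated by bisection so the event
  probability 1 − (1 − e^{−λc})/(λc) matches the target event fraction.
  PFS is capped at OS by default (`enforce_pfs_le_os = True`); the cap is
  switched off when marginal-law recovery is being tested.
* **Expression**: centroids share an N(5, 1) log2 baseline with disjoint
  128-gene marker blocks elevated by `marker_effect`; a sample draws its
  subtype centroid plus N(0, `noise_sd`) gene noise, is mapped to counts via
  mean 2^μ − 1 and negative-binomial sampling (`nb_dispersion = 10`;
  Poisson at ∞). A fraction of samples (`unclassifiable_fraction = 35/148`)
  is *signal-free*: a per-sample permutation of the mean-centroid baseline,
  so it correlates with no centroid — these emulate the samples the SSP
  fails on and exercise the rescue path.
* **Covariates**: sex, ECOG PS, prior therapy, smoking, KRAS G12C drawn at
  the published baseline frequencies, independently of subtype.

### Parameter defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| `n_genes` / `n_marker_per_subtype` | 384 / 128 | published panel size, three disjoint marker blocks |
| `marker_effect` | 2.0 | ≈ 2 log2-fold marker elevation; inter-centroid correlation < 0.3 |
| `noise_sd` | 0.5 | sample-to-centroid correlation high enough for ≥95% SSP recovery, low enough to leave the decision non-trivial |
| `nb_dispersion` | 10.0 | moderate RNA-seq overdispersion |
| `unclassifiable_fraction` | 35/148 | the published fraction of samples the SSP could not call |
| `n_outliers` / `outlier_shift` | 0 / 4.0 | outliers injected only in QC-focused experiments (see §2 caveat) |
| `censor_rate["os"]` | 43/148 | published OS censoring fraction |
| `censor_rate["pfs"]` | 0.10 | not published; a realistic PFS censoring rate for a refractory NSCLC trial |

### What it does not emulate

* No correlation between expression subtype and baseline covariates.
* No dependence between a patient's PFS and OS beyond the PFS ≤ OS cap
  (no shared frailty).
* Proportional hazards hold exactly (exponential times), whereas real KM
  curves cross and plateau.
* Gene-gene correlation beyond block membership is absent; library-size
  variation is not simulated (counts are already depth-comparable).

## 7. Numerical conventions

* All randomness flows from one integer seed through
  `np.random.SeedSequence(seed).spawn(...)`; derived seeds are reduced
  mod 2³¹ − 1. Identically-configured runs are byte-identical.
* Sorting uses stable `mergesort`/`argsort(kind="stable")` wherever order
  feeds a decision (quantile normalization, argmax tie-breaks).
* Output tables are written with `float_format = "%.6g"`; JSON with sorted
  keys and no timestamps, so reruns hash identically.
* Geometric-mean HR over replicates is exp(mean log ĤR) — the natural
  average for a ratio estimand.

## 8. Validation at scale (problem sizes used in tests)

* KM median round trip: 100,000 exponential draws, recovery within 2%.
* HR recovery: 1,000 two-arm replicates per scenario at the published cell
  sizes; geometric-mean ĤR within 15% of the generating HR and 95% Wald CI
  coverage within [0.93, 0.97].
* Brookmeyer-Crowley CI: empirical coverage over 300 replicates within
  [0.90, 0.995].
* Logistic LRT null: 200 null replicates of n = 400; mean statistic ≈ 1 and
  Kolmogorov-Smirnov uniformity of p-values.

## 9. Limitations

* The generator's exponential survival model cannot produce the
  non-proportional-hazard shapes real subtype-stratified KM curves show.
* The permutation null permutes genes independently, which destroys
  gene-gene correlation; on strongly co-expressed panels the null maxima are
  slightly anti-conservative.
* The rescue forest is only as good as the labeled reference; with the
  synthetic reference it is near-perfect, which overstates real-data rescue
  accuracy.
* PFS censoring rate and covariate independence are assumptions, not
  published facts.
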