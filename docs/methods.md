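# Methods

This note documents the statistical procedures implemented in `pathsub`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data tests do and do not demonstrate.

## Single-sample pathway scoring

Scores are a rank-based weighted random walk computed independently per
sample (the ssGSEA family).  Within each sample, genes get average ranks
(ties averaged; higher expression → higher rank).  For a gene set *S* the
walk steps through genes in descending rank order, incrementing a hit curve
by the member's rank weight (weight exponent 1, normalised by the total
member weight) and a miss curve by 1/(N − |S|); the score is the mean of
(hit − miss) over all N positions.  Consequences that the tests rely on:

- scores depend only on within-sample ranks, so they are invariant under any
  strictly monotone per-sample transform (scaling, log, quantile maps);
- the procedure is fully deterministic, including tie handling.

A Gaussian-kernel ECDF variant (the other common kernel) is deliberately not
implemented; the rank-walk variant is the package's single scoring method
because determinism and monotone invariance make every downstream claim
testable.  Set-size bounds default to [5, 5000] effective genes after
intersection with the expression universe; out-of-range sets are dropped and
logged, not errors.

Scoring may be run before or after de-duplication; the two orders commute at
the level of the retained sets' scores because each set is scored
independently.

## Jaccard de-duplication

Greedy filter at threshold 0.60 (inclusive): sets are visited in descending
size, ties by canonical-source rank then name, and a set is removed when its
Jaccard similarity to any already-retained set reaches the threshold.
Because larger sets are visited first, the retained representative of an
overlapping pair always has at least as much unique content as the removed
set.  The procedure is idempotent and the removal log records (removed,
kept, J).  The visitation order is part of the contract: any fixed order
gives a valid greedy solution, but reproducibility requires documenting one.

## Consensus subtyping

- **Distance.** Minkowski distance between sample columns of the score
  matrix; exponent p = 2 by default (exposed as a parameter).
- **PAM.** BUILD initialisation followed by best-improvement SWAP to a local
  optimum; deterministic for a fixed input order with ties resolved toward
  the smaller index.  On 9-point toys the SWAP optimum coincides with the
  exhaustive medoid search (asserted in the acceptance suite).
- **Resampling.** 80 % of samples, 10 repetitions by default (the
  conventional setting; statistically thin, and the tests use more
  repetitions where stability itself is under test).  Subsampling is
  *identity-keyed*: each (seed, repetition, sample-name) triple is hashed to
  a uniform score and the lowest 80 % are kept.  This keeps every run
  reproducible from the seed while making the consensus matrix equivariant
  under permutations of the sample order — a property position-indexed
  resampling cannot have.
- **Consensus.** C_ij = co-clustering count / co-sampling count; pairs never
  co-sampled get 0 and are counted in a coverage warning.  Per-k labels come
  from PAM on 1 − C.
- **Choice of k.**  Two gates: (i) *stability floor* — every cluster's mean
  within-cluster consensus must reach 0.85.  The floor is applied per
  cluster (equivalently to the minimum over clusters) rather than to the
  cluster-average: an over-split solution hides its two unstable fragments
  (e.g. 0.79 and 0.84) behind an average pulled up by the pure clusters.
  Singleton clusters contribute 0, as they carry no stable-pair evidence.
  (ii) *CDF gain* — the area under the consensus CDF must still be growing
  (relative delta-area > 0.05 by default) at k; past the true cluster
  number the area gain collapses because further splits only convert stable
  1-entries into intermediate values.  The chosen k is the largest candidate
  passing both gates; if none passes the floor, the argmax-consensus k is
  returned with a warning, never silently.
- **Silhouette refinement.** Iteratively, each negative-width sample is
  offered to its b(i)-minimising neighbour cluster and moved only if its own
  width improves; moves that would empty a cluster are rejected; an
  iteration that fails to raise the overall mean width is rolled back.  The
  overall mean silhouette is therefore non-decreasing across iterations by
  construction.  Refinement reassigns rather than removes samples; removal
  is a deliberate non-feature (dropping patients changes the cohort).

## Mutational signatures

- **96-context catalog.** SNVs with purine reference are reverse-complemented
  (substitution and both flanking bases) into the pyrimidine frame, leaving
  6 substitution types × 16 flank pairs = 96 classes in a fixed
  substitution-major row order.  Column sums equal per-sample SNV counts by
  construction and are asserted.  Doublet substitutions are retained and
  flagged but excluded from the 96-context matrix (they form their own
  class system); contexts containing ambiguous bases are dropped row-wise
  with counts.
- **Extraction.** Multiplicative-update NMF under generalized KL divergence,
  the standard model for count catalogs.  The update guarantees a
  non-increasing objective; the recorded trace is asserted monotone to a
  1e-6 relative tolerance (floating-point slack).  Per rank, the best of 30
  seeded restarts by final objective is kept.  Rank 1 uses the closed-form
  fixed point (profile = normalised row marginal).
- **Rank choice.** Cophenetic coefficient of the restart-consensus matrix of
  dominant-signature co-assignment (average-linkage tree vs consensus
  distances).  The chosen rank is the last before the first drop exceeding
  0.02; with no such drop, the argmax.  Rank selection on mutation data is
  intrinsically heuristic; the recovery guarantees in the acceptance suite
  are therefore stated at the planted rank, not through the selector.
- **Reference matching.** Cosine similarity per extracted signature against
  a catalogue in the same fixed row order (validated, with a reindexing
  hint on mismatch).  Default is an independent argmax per signature — two
  extracted signatures may share a best reference, which is informative —
  with a Hungarian one-to-one option for recovery benchmarking.
- **Refitting.** Non-negative least squares per sample against
  column-stochastic references; bootstrap stability by resampling each
  sample's mutations multinomially at its observed total (probabilities =
  the observed spectrum) and refitting, 100 replicates by default.
  Exposures are reported both raw and as per-sample fractions.
- **TMB** is reported as raw per-sample counts (total and SNV-only); no
  per-megabase normalisation is applied because no capture size is modelled.

## Co-expression network and hub genes

The network is unsigned: `a_ij = |cor(x_i, x_j)|^β`.  β is the smallest
power whose connectivity distribution passes a signed scale-free fit
(R² ≥ 0.8 with negative slope over log-binned connectivity), argmax R²
otherwise.  The topological overlap is

`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

with unit diagonal and entries machine-checked in [0, 1].  Network
construction and GS/MM statistics expect roughly homoscedastic inputs; the
CLI therefore log2(x+1)-transforms FPKM-like matrices by default (raw
heavy-tailed FPKM attenuates every Pearson-based statistic downstream).

Modules are average-linkage clusters of 1 − TOM under a static cut.  The
default cut is chosen adaptively: all merge heights are scanned for the
maximal number of clusters of at least `min_module_size` (default 30)
members, and among tied heights the cut at the lower edge of the largest
between-merge gap wins — the longest-branch heuristic.  A fixed fraction of
the tree height is brittle here because TOM distances on sparse networks
concentrate just below 1: the band between "modules complete" and
"background attaches" can be narrower than 1 % of the tree height.  The
adaptive cut is deterministic, scale-free, and reduces to the intuitive cut
on well-separated data; an explicit `cut_height` restores the static
behaviour.  Sub-floor clusters become `grey`; surviving modules are named
by decreasing size along the conventional colour sequence with ties broken
by member names, so labels do not depend on gene input order.

Module eigengenes are the first principal component over samples of the
standardised module block, sign-anchored to a positive mean gene loading
(removing the SVD sign ambiguity).  MM = cor(gene, own-module eigengene);
GS = cor(gene, one-hot subtype indicator), one column per subtype.  Hub
genes per subtype: |GS| > 0.3 and |MM| > 0.8, ranked by |GS| descending with
|MM| then name as tie-breaks, top 10; fewer qualifiers are returned in full
with a warning.

## Subtype classifier

One hidden layer of six logistic units and a softmax output, trained by
full-batch gradient descent on cross-entropy (learning rate 0.01, 2000
epochs, no regularisation — stable for ~10–50 input genes).  Each step is
accepted only if the loss does not increase; otherwise the rate is halved
and the step retried, so the recorded loss trace is non-increasing by
construction and training is bit-reproducible from the seed.  Per-gene
standardisation parameters are fitted on the training split only and frozen
into the model; the serialised JSON artifact carries genes, scalers,
weights, config and seed.

External cohorts are harmonised by per-gene z-scoring *within* the external
dataset — a deliberate, recorded assumption that removes platform location
and scale but not distribution-shape differences.  At least 80 % of model
genes must be present; missing genes are imputed at the standardised mean
(0) with a warning.  Evaluation: stratified 80:20 hold-out at training
time, and stratified 5-fold cross-validation with a fresh model and fresh
scalers per fold; metrics are accuracy, per-class/macro/weighted F1 and
one-vs-rest AUC; folds shrink with a warning when the smallest class is
smaller than the fold count.

## Statistical screens

- Screens threshold on **raw p-values** by default, matching the printed
  conventions of the analyses they mirror; Benjamini–Hochberg adjusted
  p-values are always computed alongside so FDR control is a column away.
- **Differential expression** (one-vs-rest): Welch t on log2(x+1);
  log2 fold change on group means, log2(mean+1) scale; default cut
  p < .05 and |log2FC| > 2.  Welch rather than moderated statistics: with
  per-gene df ≥ 100 in the intended designs, moderation adds an untestable
  prior for negligible gain.
- **Enrichment-score differential**: enrichment scores can be negative, so
  "fold change" is ill-defined; the ratio is used only when both group means
  are positive, otherwise the absolute mean difference, and the mode is
  recorded per row.
- **ANOVA screen**: one-way F per feature; k = 2 reduces exactly to the
  pooled t (F = t²).  Zero within-group variance is flagged degenerate
  (p = 0 when means differ, NaN when globally constant), never silently
  dropped.
- **Mutation pair patterns**: two-sided Fisher exact per gene pair;
  direction co-occurrence (OR > 1) vs exclusivity.  Verified equivalent to
  exhaustive hypergeometric enumeration on every 2×2 table with n ≤ 30.
- **Correlation screens**: Pearson r with t-distributed p, matched-feature
  or all-pairs pairing, positive or absolute sign mode — covering the
  CNV–mRNA (positive, r > .5), CNV–mRNA–protein (intersection of pairwise
  screens), methylation–expression (absolute) and signature–expression
  (positive, r > .2) variants.
- **Survival**: Kaplan–Meier curves and k-group log-rank via lifelines;
  medians reported as not-reached (NaN) when the curve stays above 0.5.
  Univariate Cox is an in-package Newton fit of the partial likelihood with
  Breslow tie handling; on continuous (tie-free) data it agrees with the
  Efron-based reference implementation to ~1e-6, and its score test equals
  the two-group log-rank statistic exactly for a binary covariate.
- **Maximally selected cutpoints**: scan of the midpoints between distinct
  score values with both groups ≥ 10 % of the cohort; the cutpoint maximises
  the log-rank chi-square.  Significance is assessed by permutation of the
  scores (1000 by default), which accounts for the selection of the maximum.
  The naive single-test chi-square p is reported for reference only and is
  anti-conservative — under the null it rejects at well above nominal rate,
  which the acceptance suite measures rather than assumes.

## Drug sensitivity and immunophenotypes

A (cell line, drug) experiment is *sensitive* when AUC > 0.7; the direction
of the AUC convention differs across database releases, so it is an explicit
flag with a loud warning naming the convention in effect.  A drug belongs to
a subtype when at least one line of that subtype is sensitive
(presence-based counting; a minimum-fraction variant is available).  The
universal / subtype-specific / shared-but-not-universal blocks are disjoint
and cover all sensitive drugs — an identity asserted in tests.  Raising the
threshold can only shrink the sensitive sets (monotonicity, also asserted).

Signature–drug matching joins per-sample exposure fractions above an
activity floor (default 0.05) with a (signature, drug, direction) marker
table; 'sensitive' markers become recommendations, 'resistant' markers
contraindications.

Immunophenotyping z-scores a cell-type×sample score matrix, consensus-
clusters samples at k = 2, and labels the class with the higher mean
aggregate z-score immune-inflamed, the other immune-desert.

## Synthetic data: what it emulates, and what it does not

`make_cohort` plants k balanced subtypes as +`effect`·σ mean shifts on
disjoint blocks of 30 marker genes (of 500) on the log scale, with
log-normal noise (σ = 1) exponentiated to an FPKM-like positive scale.
Survival is exponential per subtype (default hazards geometrically spaced
over 0.001–0.004 per day, i.e. median survivals of roughly 170–690 days)
with independent uniform censoring on [0, M], M solved so the expected
censored fraction matches `censor_rate` (default 0.2).  Defaults follow the
intended study scale: cohorts of ~150–160 samples, five subtypes.
Companion generators produce gene sets with controlled pairwise Jaccard
(nearest feasible integer overlap, rejecting infeasible requests), mutation
catalogs drawn multinomially from planted exposure-weighted signature
mixtures with contexts written explicitly (no reference genome), and
CNV/protein/methylation layers with tunable cis-correlation (methylation
through a logistic link, guaranteeing betas in [0, 1] and negative
coupling).

Real data differ in ways the generator deliberately omits: correlated
(non-block) gene–gene structure, library-size and batch effects, informative
censoring, subtype imbalance, overlapping marker programmes, and
sequencing-depth noise in mutation spectra.  Passing the recovery suite
therefore shows the pipeline is *correct and well-calibrated under its own
assumptions* — it does not certify performance on any real cohort.

## Numerical conventions

- All generators and algorithms take explicit integer seeds; child seeds are
  spawned deterministically and kept below 2³¹.
- TSVs are written with a fixed `%.6g` float format and LF endings, making
  same-seed reruns byte-identical (asserted end-to-end through the CLI).
- KL-NMF uses an ε of 1e-12 inside divisions; profile columns are
  renormalised to sum 1 with the scale moved into H.
- PAM, de-duplication and hub ranking break every tie deterministically
  (smaller index / larger set / lexicographic name), so no result depends on
  dict or sort instability.

## Known limitations

- "Agglomerative PAM" in the consensus literature is a misnomer; this
  package implements PAM proper, and no agglomerative fallback exists.
- The maxstat permutation p is Monte-Carlo (resolution 1/(n_perm+1)); the
  closed-form selection-corrected approximation is not implemented.
- The NMF rank selector and the consensus k selector are heuristics with
  documented gates; both return full decision traces so a disagreeing
  analyst can overrule them without rerunning.
- The classifier is intentionally minimal (no regularisation, no early
  stopping); it is a subtype *transfer* device over ~dozens of hub genes,
  not a general-purpose expression classifier.
- Off-the-shelf baseline classifiers (trees, forests, SVM, kNN, naive
  Bayes) are out of scope; the evaluation interface accepts any model that
  follows the train/predict contract.
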