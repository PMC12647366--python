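# pathsub

Pathway-activity subtyping of bulk tumour transcriptomes, with the
surrounding genomic analyses that anchor the subtypes mechanistically.

Tumour cohorts such as glioblastoma (GBM) are heterogeneous at the level of
coordinated pathway activity rather than single genes.  `pathsub` implements
a complete, reproducible pipeline for discovering and validating
pathway-based patient subtypes:

1. **Single-sample pathway scoring** — for each sample, genes are ranked and
   a weighted Kolmogorov–Smirnov random walk over each gene set *S* gives an
   enrichment score

   `ES(S, s) = (1/N) Σ_i [ P_hit(i) − P_miss(i) ]`,

   where `P_hit` accumulates the rank weights of set members and `P_miss`
   the non-members.  Scores depend only on within-sample ranks, so any
   monotone normalisation of the expression leaves them unchanged.
2. **Signature de-duplication** — greedy removal of gene sets with pairwise
   Jaccard similarity ≥ 0.60, keeping the representative with more unique
   content.
3. **Consensus subtyping** — partitioning-around-medoids (PAM, BUILD + SWAP)
   on Minkowski distances over the signature×sample score matrix, resampling
   80 % of samples over repeated runs.  The consensus matrix entry
   `C_ij = (#times i,j co-cluster)/(#times co-sampled)` feeds the choice of
   k (every cluster's mean consensus ≥ 0.85 plus a CDF delta-area gain) and a
   silhouette-based refinement that reassigns negative-width samples.
4. **Mutational signatures** — strand-collapsed 96-trinucleotide-context
   catalogs, de novo extraction by KL-divergence NMF (`V ≈ WH`, W
   column-stochastic), cosine matching against a reference catalogue, and
   exposure refitting by non-negative least squares with multinomial
   bootstrap stability (100 replicates by default).
5. **Hub genes** — an unsigned weighted co-expression network
   (`a_ij = |cor|^β`, topological overlap matrix), module detection, and
   per-subtype hub selection at |GS| > 0.3 and |MM| > 0.8.
6. **Subtype classifier** — a one-hidden-layer (6 logistic units) softmax
   network over standardised hub-gene expression, with 80:20 held-out and
   5-fold cross-validated evaluation, transferable to external cohorts by
   within-dataset z-scoring.
7. **Downstream screens** — one-vs-rest differential expression, mutation
   co-occurrence/exclusivity (Fisher exact), CNV–mRNA–protein and
   methylation–expression correlation screens, Kaplan–Meier/log-rank and
   univariate Cox survival analysis, maximally selected survival cutpoints,
   and GDSC-style drug-sensitivity set logic with two-class
   immunophenotyping.

A first-class synthetic-cohort generator (`pathsub.synthetic`) plants every
piece of structure the pipeline assumes — expression subtypes of tunable
separation, signature-exposure mixtures, cis-correlated omics layers,
subtype-dependent exponential survival — so the whole pipeline is testable
without any download.

## Worked example

```python
import pathsub as ps
from sklearn.metrics import adjusted_rand_score

cohort = ps.make_cohort(n_samples=150, n_genes=500, k=5, effect=2.0, seed=0)
collection = ps.marker_geneset_collection(cohort, n_random=20, seed=1)
E = ps.score_enrichment(cohort.expression, collection)
result = ps.consensus_cluster(E, k_range=range(2, 8), reps=10, seed=2)
k, trace, warned = ps.select_k(result)
print(trace[["min_within_consensus", "delta_area"]].round(3))
print(f"chosen k = {k}")
D = ps.consensus.minkowski_distances(E.scores)
report, labels = ps.silhouette_refine(D, result.labels[k])
print(f"mean silhouette = {report.overall_mean:.3f}")
print(f"ARI vs planted subtypes = {adjusted_rand_score(cohort.labels, labels):.3f}")
```

prints

```
   min_within_consensus  delta_area
k
2                 0.906         inf
3                 0.663       0.638
4                 0.665       0.158
5                 1.000       0.078
6                 0.899       0.024
7                 0.736       0.024
chosen k = 5
mean silhouette = 0.374
ARI vs planted subtypes = 1.000
```

Reading the trace: k = 5 is the largest candidate whose least-stable cluster
still has mean consensus ≥ 0.85 *and* whose consensus-CDF area still grows
appreciably over k − 1 (k = 6 is stable on average but its area gain has
collapsed to 0.024).  The refined labels recover the five planted subtypes
exactly.

The same pipeline is available from the shell; every stage takes an explicit
seed and writes byte-reproducible TSV/JSON:

```bash
pathsub simulate --n-samples 150 --k 5 --seed 0 --outdir cohort/
pathsub enrich   --expr cohort/expression.tsv --gmt cohort/genesets.gmt --out scores.tsv
pathsub cluster  --scores scores.tsv --k-min 2 --k-max 7 --seed 2 --outdir subtypes/
pathsub signatures --maf cohort/mutations.maf.tsv --seed 3 --outdir sigs/
pathsub hubs     --expr cohort/expression.tsv --labels subtypes/labels.tsv --outdir hubs/
pathsub train    --expr cohort/expression.tsv --labels subtypes/labels.tsv \
                 --seed 4 --model-out model.json
```

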