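"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants k expression subtypes as mean shifts (in within-gene SD
units, on the log scale) on disjoint marker-gene blocks, draws subtype-
dependent exponential survival with independent uniform censoring, and can
emit matched gene-set collections with controlled Jaccard overlap, mutation
catalogs from planted signature-exposure mixtures, and CNV/protein/
methylation layers cis-correlated with expression.  Every generator is
seed-deterministic: the same seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._utils import rng_from_seed
from .genesets import GeneSetCollection

__all__ = [
    "SyntheticCohort",
    "PlantedSignatureModel",
    "make_cohort",
    "make_geneset_collection",
    "make_signature_model",
    "make_mutation_catalog",
    "make_paired_omics",
    "marker_geneset_collection",
]


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame          # gene x sample, FPKM-like (>= 0, finite)
    labels: pd.Series                 # sample -> subtype index in 1..k
    survival: pd.DataFrame            # sample, time (days, > 0), event in {0,1}
    params: dict = field(default_factory=dict)
    marker_blocks: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = int(self.params.get("k", self.labels.max()))
        if not self.labels.isin(range(1, k + 1)).all():
            raise ValueError("every sample must carry a label in 1..k")
        if not (self.survival["time"] > 0).all():
            raise ValueError("survival times must be strictly positive")
        X = self.expression.to_numpy()
        if not np.isfinite(X).all() or (X < 0).any():
            raise ValueError("expression must be finite and non-negative")


@dataclass
class PlantedSignatureModel:
    """Generative twin of an NMF factorisation: column-stochastic 96-context
    profiles and non-negative per-sample exposures."""

    profiles: pd.DataFrame            # 96 x r, columns sum to 1
    exposures: pd.DataFrame           # r x samples, >= 0
    seed: int | None = None

    def __post_init__(self) -> None:
        colsum = self.profiles.sum(axis=0).to_numpy()
        if not np.allclose(colsum, 1.0, atol=1e-9):
            raise ValueError("each profile column must sum to 1 (tol 1e-9)")
        if (self.exposures.to_numpy() < 0).any():
            raise ValueError("exposures must be non-negative")


def _censoring_horizon(hazards: np.ndarray, counts: np.ndarray, censor_rate: float) -> float:
    """Horizon M such that C ~ U(0, M) censors the hazard mixture at the
    requested rate.  For T ~ Exp(h), P(T > C) = (1 - exp(-hM)) / (hM), which
    decreases from 1 (M -> 0) to 0 (M -> inf); the mixture average is solved
    by bisection."""

    w = counts / counts.sum()

    def censored_frac(M):
        lam = hazards * M
        return float(np.sum(w * (1.0 - np.exp(-lam)) / lam))

    lo, hi = 1e-9, 1.0
    while censored_frac(hi) > censor_rate:
        hi *= 2
        if hi > 1e12:
            raise RuntimeError("failed to bracket censoring horizon")
    return optimize.brentq(lambda M: censored_frac(M) - censor_rate, lo, hi)


def make_cohort(
    n_samples: int = 160,
    n_genes: int = 500,
    k: int = 5,
    effect: float = 2.0,
    censor_rate: float = 0.2,
    hazards=None,
    seed: int = 0,
    markers_per_subtype: int = 30,
    sigma: float = 1.0,
) -> SyntheticCohort:
    """Cohort with k planted expression subtypes and subtype-dependent survival.

    Expression is log-normal: per-gene baseline log-means, within-gene log-SD
    ``sigma``, and a +``effect``*sigma shift on each subtype's disjoint block
    of ``markers_per_subtype`` marker genes; values are exponentiated to an
    FPKM-like scale.  Survival times are exponential with the subtype's
    hazard (per day); censoring is by an independent uniform time on
    [0, M] with M solved so the expected censored fraction equals
    ``censor_rate``.  Labels are balanced round-robin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < k:
        raise ValueError("n_samples must be >= k")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if markers_per_subtype * k > n_genes:
        raise ValueError("marker blocks exceed the number of genes")
    if hazards is None:
        # per-day rates spanning median survivals of ~690 down to ~170 days
        hazards = np.geomspace(0.001, 0.004, k)
    hazards = np.asarray(hazards, dtype=float)
    if hazards.shape != (k,) or (hazards <= 0).any():
        raise ValueError("hazards must be k positive per-subtype rates")

    rng = rng_from_seed(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    labels = np.arange(n_samples) % k + 1

    base = rng.normal(1.0, 1.0, size=n_genes)
    logx = base[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_samples))
    marker_blocks: dict[int, list[str]] = {}
    for s in range(k):
        block = slice(s * markers_per_subtype, (s + 1) * markers_per_subtype)
        marker_blocks[s + 1] = genes[block]
        logx[block, :][:, labels == s + 1] += effect * sigma
    expression = pd.DataFrame(np.exp(logx), index=genes, columns=samples)

    t_event = rng.exponential(1.0 / hazards[labels - 1])
    event = np.ones(n_samples, dtype=int)
    time = t_event
    if censor_rate > 0:
        counts = np.bincount(labels - 1, minlength=k).astype(float)
        M = _censoring_horizon(hazards, counts, censor_rate)
        c = rng.uniform(0.0, M, size=n_samples)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-9)

    survival = pd.DataFrame({"sample": samples, "time": time, "event": event}
                            ).set_index("sample")
    params = dict(n_samples=n_samples, n_genes=n_genes, k=k, effect=effect,
                  censor_rate=censor_rate, hazards=list(map(float, hazards)),
                  seed=int(seed), markers_per_subtype=markers_per_subtype,
                  sigma=sigma)
    return SyntheticCohort(expression, pd.Series(labels, index=samples, name="subtype"),
                           survival, params, marker_blocks)


def _shared_count(set_size: int, target_j: float) -> int:
    """Shared-gene count for two equal-size sets whose Jaccard is closest to
    the target: argmin over s in 0..m of |s/(2m - s) - J| (ties -> larger s)."""
    m = set_size
    s_grid = np.arange(m + 1)
    j_grid = s_grid / (2 * m - s_grid)
    err = np.abs(j_grid - target_j)
    # ties broken toward the larger shared count
    return int(s_grid[np.lexsort((-s_grid, err))[0]])


def make_geneset_collection(
    n_sets: int,
    set_size: int,
    overlap_matrix,
    universe,
    seed: int = 0,
) -> GeneSetCollection:
    """Equal-size gene sets with controlled pairwise Jaccard overlap.

    ``overlap_matrix`` is a scalar target applied to every pair or an
    n_sets x n_sets symmetric matrix of targets in [0, 1].  Sets are built
    sequentially, borrowing the nearest-feasible number of shared genes from
    each earlier set; a request that cannot be realised within +-0.05 of the
    nearest-feasible Jaccard (e.g. conflicting overlaps or an exhausted
    universe) is rejected with a diagnostic.
    """
    universe = list(universe)
    J = np.asarray(overlap_matrix, dtype=float)
    if J.ndim == 0:
        J = np.full((n_sets, n_sets), float(J))
    np.fill_diagonal(J, 1.0)
    if J.shape != (n_sets, n_sets) or (J < 0).any() or (J > 1).any():
        raise ValueError("overlap targets must form an n_sets x n_sets matrix in [0,1]")
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")

    rng = rng_from_seed(seed)
    pool = list(rng.permutation(universe))
    built: list[list[str]] = []
    for i in range(n_sets):
        genes: list[str] = []
        for j_prev, prev in enumerate(built):
            s = _shared_count(set_size, J[i, j_prev])
            candidates = [g for g in prev if g not in genes]
            take = [g for g in candidates[:s]]
            if len(take) < s:
                raise ValueError(
                    f"infeasible overlap request: set {i} needs {s} shared genes "
                    f"with set {j_prev}, only {len(take)} available"
                )
            genes.extend(take)
        if len(genes) > set_size:
            raise ValueError(
                f"infeasible overlap request: set {i} needs {len(genes)} shared "
                f"genes but set_size is {set_size}"
            )
        fresh = [g for g in pool if g not in set(genes) and
                 not any(g in set(b) for b in built)]
        need = set_size - len(genes)
        if need > len(fresh):
            raise ValueError("universe too small for the requested overlaps")
        genes.extend(fresh[:need])
        built.append(genes)

    coll = GeneSetCollection(
        {f"set{i:03d}": genes for i, genes in enumerate(built)},
        {f"set{i:03d}": "synthetic" for i in range(n_sets)},
    )
    # verify realised overlaps against the nearest-feasible targets
    for i in range(n_sets):
        for j in range(i):
            s = _shared_count(set_size, J[i, j])
            feasible_j = s / (2 * set_size - s)
            realised = len(set(built[i]) & set(built[j])) / len(set(built[i]) | set(built[j]))
            if abs(realised - feasible_j) > 0.05 + 1e-12:
                raise ValueError(
                    f"infeasible overlap request: sets {i},{j} realised J={realised:.3f} "
                    f"vs feasible target {feasible_j:.3f}"
                )
    return coll


def marker_geneset_collection(cohort: SyntheticCohort, n_random: int = 0,
                              random_size: int = 30, seed: int = 0) -> GeneSetCollection:
    """The cohort's planted marker blocks as gene sets, optionally padded with
    random sets drawn from the non-marker universe (the scoring collection
    used for pipeline-level recovery checks)."""
    sets = {f"marker_subtype{s}": list(genes) for s, genes in cohort.marker_blocks.items()}
    source = {name: "marker" for name in sets}
    if n_random:
        rng = rng_from_seed(seed)
        marker_genes = {g for gs in cohort.marker_blocks.values() for g in gs}
        others = [g for g in cohort.expression.index if g not in marker_genes]
        for i in range(n_random):
            sets[f"random{i:03d}"] = list(rng.choice(others, size=random_size, replace=False))
            source[f"random{i:03d}"] = "random"
    return GeneSetCollection(sets, source)


def make_signature_model(
    n_signatures: int = 3,
    n_samples: int = 150,
    concentration: float = 0.1,
    exposure_concentration: float = 1.0,
    seed: int = 0,
) -> PlantedSignatureModel:
    """Planted signature profiles (sparse Dirichlet over the 96 contexts) and
    Dirichlet exposure fractions per sample."""
    from .mutsig import CONTEXT_CLASSES

    rng = rng_from_seed(seed)
    W = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    H = rng.dirichlet(np.full(n_signatures, exposure_concentration), size=n_samples).T
    profiles = pd.DataFrame(W, index=CONTEXT_CLASSES,
                            columns=[f"planted{j+1}" for j in range(n_signatures)])
    exposures = pd.DataFrame(H, index=profiles.columns,
                             columns=[f"s{i:03d}" for i in range(n_samples)])
    return PlantedSignatureModel(profiles, exposures, seed=int(seed))


def make_mutation_catalog(
    model: PlantedSignatureModel,
    n_mut_per_sample: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """MAF-lite table drawn multinomially from each sample's exposure-weighted
    mixture of profiles; trinucleotide contexts are written explicitly in the
    ``ref_context`` column so no reference genome is needed."""
    from .mutsig import parse_context_class

    rng = rng_from_seed(seed)
    W = model.profiles.to_numpy()
    rows = []
    pos_counter = 1
    for sample in model.exposures.columns:
        h = model.exposures[sample].to_numpy()
        tot = h.sum()
        if tot <= 0:
            raise ValueError(f"sample {sample!r} has zero total exposure")
        p = W @ (h / tot)
        counts = rng.multinomial(n_mut_per_sample, p)
        for cls_idx in np.nonzero(counts)[0]:
            five, ref, alt, three = parse_context_class(model.profiles.index[cls_idx])
            for _ in range(int(counts[cls_idx])):
                rows.append((sample, "chr1", pos_counter, ref, alt, "SNP",
                             five + ref + three))
                pos_counter += 1
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                       "variant_type", "ref_context"])


def make_paired_omics(
    cohort: SyntheticCohort,
    cis_genes: int = 50,
    r_target: float = 0.8,
    seed: int = 0,
):
    """CNV, protein and methylation layers cis-linked to expression.

    For the first ``cis_genes`` genes, CNV is built to correlate with that
    gene's (standardised) expression at Pearson r ~ r_target, protein with
    CNV likewise, and the methylation beta decreases monotonically with
    expression (negative correlation).  Remaining genes get independent
    noise.  Betas are bounded in [0, 1] by construction (logistic link).
    """
    if not (0.0 < r_target < 1.0):
        raise ValueError("r_target must be in (0, 1)")
    if cis_genes > cohort.expression.shape[0]:
        raise ValueError("cis_genes exceeds the number of genes")
    rng = rng_from_seed(seed)
    X = cohort.expression.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    zx = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    r = r_target
    mix = np.sqrt(1.0 - r * r)
    cnv = rng.normal(size=(n_genes, n_samples))
    prot = rng.normal(size=(n_genes, n_samples))
    meth_latent = rng.normal(size=(n_genes, n_samples))
    cis = slice(0, cis_genes)
    cnv[cis] = r * zx[cis] + mix * cnv[cis]
    zc = (cnv[cis] - cnv[cis].mean(axis=1, keepdims=True)) / cnv[cis].std(axis=1, keepdims=True)
    prot[cis] = r * zc + mix * prot[cis]
    meth_latent[cis] = -(r * zx[cis]) + mix * meth_latent[cis]
    beta = special.expit(meth_latent)

    idx, cols = cohort.expression.index, cohort.expression.columns
    return (pd.DataFrame(cnv, index=idx, columns=cols),
            pd.DataFrame(prot, index=idx, columns=cols),
            pd.DataFrame(beta, index=idx, columns=cols))
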