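"""Gene-set collections: GMT I/O, Jaccard redundancy filtering, and
single-sample pathway-activity scoring.

The enrichment score is a rank-based weighted random walk computed
independently per sample (ssGSEA style): genes are ranked within each sample
(average ranks on ties), the walk steps up through set members in proportion
to their rank weight and down through non-members uniformly, and the score is
the area between the two cumulative curves normalised by the universe size.
It therefore depends only on within-sample ranks and is invariant under any
strictly monotone per-sample transform of the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentMatrix",
    "read_gmt",
    "write_gmt",
    "jaccard",
    "dedup_collection",
    "score_enrichment",
    "differential_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with per-set provenance.

    ``sets`` maps set name -> list of gene ids (duplicates removed, first
    occurrence order kept); ``source`` maps set name -> provenance string.
    """

    sets: dict[str, list[str]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.source.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: list(self.sets[n]) for n in names},
            {n: self.source[n] for n in names},
        )


@dataclass
class EnrichmentMatrix:
    """Signature x sample pathway-activity scores.

    ``scores`` rows correspond 1:1 to the retained signatures; ``dropped``
    records sets excluded by the size filter with the reason.
    """

    scores: pd.DataFrame
    universe_size: int
    settings: dict
    dropped: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValueError("enrichment scores contain NaN")


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, genes...).

    Duplicate gene ids within a set are collapsed; a duplicated set name or a
    line with fewer than three fields is an error (reported with its line
    number).
    """
    sets: dict[str, list[str]] = {}
    source: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicated set name {name!r}")
            seen: dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(g, None)
            if not seen:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = list(seen)
            source[name] = desc
    return GeneSetCollection(sets, source)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, coll.source.get(name, "")] + list(genes)) + "\n")


def jaccard(a, b) -> float:
    """|a n b| / |a u b| for two non-empty gene sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard similarity is undefined for empty sets")
    return len(a & b) / len(a | b)


def dedup_collection(
    coll: GeneSetCollection,
    threshold: float = 0.60,
    source_rank: dict[str, int] | None = None,
):
    """Greedy redundancy filter: drop any set with Jaccard >= threshold to an
    already-retained set.

    Sets are visited in descending size, ties broken by canonical-source rank
    (smaller rank = more canonical, default 0 for every source) then name
    order, so the retained representative of an overlapping pair always has
    unique content >= the removed one.  Returns ``(retained, removal_log)``
    where the log records (removed, kept, jaccard).  Idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    source_rank = source_rank or {}
    order = sorted(
        coll.sets,
        key=lambda n: (-len(coll.sets[n]), source_rank.get(coll.source.get(n, ""), 0), n),
    )
    retained: list[str] = []
    retained_sets: list[frozenset] = []
    log_rows = []
    for name in order:
        s = frozenset(coll.sets[name])
        removed = False
        for kept_name, kept_set in zip(retained, retained_sets):
            j = len(s & kept_set) / len(s | kept_set)
            if j >= threshold:
                log_rows.append({"removed": name, "kept": kept_name, "jaccard": j})
                removed = True
                break
        if not removed:
            retained.append(name)
            retained_sets.append(s)
    keep_in_input_order = [n for n in coll.sets if n in set(retained)]
    log = pd.DataFrame(log_rows, columns=["removed", "kept", "jaccard"])
    return coll.subset(keep_in_input_order), log


def _rank_walk_scores(ranks: np.ndarray, order: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Enrichment score per sample for one membership vector.

    ranks: genes x samples within-sample average ranks (higher = more
    expressed); order: genes x samples descending-rank permutations; member:
    boolean gene vector.
    """
    n_genes, _ = ranks.shape
    m_ord = member[order]                                   # genes x samples
    r_ord = np.take_along_axis(ranks, order, axis=0)
    hit_w = np.where(m_ord, r_ord, 0.0)
    hit_tot = hit_w.sum(axis=0)
    p_hit = np.cumsum(hit_w, axis=0) / hit_tot
    n_out = n_genes - int(member.sum())
    p_miss = np.cumsum(~m_ord, axis=0) / n_out
    return (p_hit - p_miss).sum(axis=0) / n_genes


def score_enrichment(
    expr: pd.DataFrame,
    coll: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 5000,
) -> EnrichmentMatrix:
    """Per-sample rank-walk enrichment scores for every retained gene set.

    Sets are intersected with the expression universe first; sets whose
    effective size falls outside [min_size, max_size] (or that would cover the
    whole universe, leaving no background) are dropped and logged.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    universe = pd.Index(expr.index)
    n_genes = len(universe)

    X = expr.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=0)                      # average ranks, ties safe
    order = np.argsort(-ranks, axis=0, kind="stable")

    rows, kept_names, dropped = [], [], []
    any_overlap = False
    for name, genes in coll.sets.items():
        member = universe.isin(genes)
        size = int(member.sum())
        if size > 0:
            any_overlap = True
        if size < min_size or size > max_size:
            dropped.append({"set": name, "effective_size": size, "reason": "size"})
            continue
        if size == n_genes:
            dropped.append({"set": name, "effective_size": size, "reason": "covers_universe"})
            continue
        rows.append(_rank_walk_scores(ranks, order, member))
        kept_names.append(name)
    if not any_overlap:
        raise ValueError("no gene set overlaps the expression universe")
    scores = pd.DataFrame(np.array(rows) if rows else np.empty((0, expr.shape[1])),
                          index=kept_names, columns=expr.columns)
    return EnrichmentMatrix(
        scores=scores,
        universe_size=n_genes,
        settings={"min_size": min_size, "max_size": max_size, "method": "rank_walk"},
        dropped=pd.DataFrame(dropped, columns=["set", "effective_size", "reason"]),
    )


def differential_enrichment(
    E: EnrichmentMatrix | pd.DataFrame,
    group_a,
    group_b,
    p_thresh: float = 0.01,
    fc_thresh: float = 2.0,
) -> pd.DataFrame:
    """Two-sample (Welch) screen of enrichment scores between sample groups.

    Because enrichment scores may be negative, a fold-change ratio is only
    meaningful when both group means are positive; otherwise the threshold is
    applied to the absolute mean difference.  The mode used is recorded per
    row in ``fc_mode``.  Output is sorted by p ascending; zero within-group
    variance in both groups yields p = NaN with ``degenerate`` flagged.
    """
    scores = E.scores if isinstance(E, EnrichmentMatrix) else E
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = scores[group_a].to_numpy(dtype=float)
    B = scores[group_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    diff = mean_a - mean_b
    both_pos = (mean_a > 0) & (mean_b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(both_pos, mean_a / mean_b, np.nan)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    pass_fc = np.where(
        both_pos,
        (ratio >= fc_thresh) | (ratio <= 1.0 / fc_thresh),
        np.abs(diff) >= fc_thresh,
    )
    flagged = (p < p_thresh) & pass_fc & ~degenerate
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": diff,
            "ratio": ratio,
            "fc_mode": np.where(both_pos, "ratio", "abs_difference"),
            "degenerate": degenerate,
            "flagged": flagged,
        },
        index=scores.index,
    )
    return out.sort_values("p", kind="stable")
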