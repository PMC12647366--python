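"""Consensus subtyping: PAM on a sample dissimilarity matrix, resampled
consensus matrices over a range of k, CDF/delta-area based selection of the
cluster number, and silhouette-based label refinement.

Resampling is identity-keyed: each (rep, sample-name) pair is mapped through
a keyed hash to a uniform score and the lowest ``subsample`` fraction of
scores is kept, so the same seed always draws the same *samples* regardless
of their order in the matrix (consensus matrices are therefore equivariant
under sample permutation).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._utils import as_distance_matrix
from .genesets import EnrichmentMatrix

__all__ = [
    "ConsensusResult",
    "SilhouetteReport",
    "pam",
    "consensus_cluster",
    "select_k",
    "silhouette_refine",
    "silhouette_widths",
]


# ---------------------------------------------------------------- PAM ------

def pam(D: np.ndarray, k: int, max_swaps: int = 200):
    """Partitioning around medoids with BUILD initialisation and
    best-improvement SWAP until a local optimum.

    Deterministic for a fixed input order (ties resolved toward the smaller
    index).  Returns ``(labels, medoids)`` with labels in 0..k-1 numbered by
    medoid order.
    """
    D = as_distance_matrix(D)
    n = D.shape[0]
    if k < 1 or k >= n:
        raise ValueError("k must satisfy 1 <= k < n")

    # BUILD: greedily add the medoid giving the largest cost reduction
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.minimum(D, dnear[:, None]).sum(axis=0)  # cost if column j added
        gain[medoids] = np.inf
        j = int(np.argmin(gain))
        medoids.append(j)
        dnear = np.minimum(dnear, D[:, j])

    medoids = np.array(medoids)
    for _ in range(max_swaps):
        Dm = D[:, medoids]                                   # n x k
        order = np.argsort(Dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = Dm[np.arange(n), nearest]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

        non = np.setdiff1d(np.arange(n), medoids)
        Dj = D[:, non]                                       # n x (n-k)
        base = np.minimum(Dj - d1[:, None], 0.0)             # i not served by removed medoid
        base_sum = base.sum(axis=0)
        best_delta, best_pair = 0.0, None
        for m_idx in range(k):
            mask = nearest == m_idx
            repl = np.minimum(Dj[mask], d2[mask, None]) - d1[mask, None]
            delta = base_sum - base[mask].sum(axis=0) + repl.sum(axis=0)
            j_best = int(np.argmin(delta))
            if delta[j_best] < best_delta - 1e-12:
                best_delta, best_pair = float(delta[j_best]), (m_idx, non[j_best])
        if best_pair is None:
            break
        m_idx, j = best_pair
        medoids = medoids.copy()
        medoids[m_idx] = j
    labels = np.argmin(D[:, medoids], axis=1)
    labels[medoids] = np.arange(k)   # each medoid belongs to its own cluster
    return labels, medoids


# ------------------------------------------------------- consensus ---------

@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]       # k -> sample x sample in [0,1]
    labels: dict[int, pd.Series]             # k -> sample -> cluster (1-based)
    per_cluster_consensus: dict[int, list]   # k -> per-cluster mean consensus
    mean_within_consensus: dict[int, float]
    min_within_consensus: dict[int, float]
    cdf: dict[int, np.ndarray]               # empirical CDF on CDF_GRID
    area: dict[int, float]                   # area under the consensus CDF
    delta_area: dict[int, float]             # relative gain over previous k
    never_cosampled: int                     # pair-count with zero denominator
    empty_cluster_flags: dict[int, bool]
    samples: list[str] = field(default_factory=list)
    k_range: list[int] = field(default_factory=list)

    CDF_GRID = np.linspace(0.0, 1.0, 101)

    def __post_init__(self) -> None:
        for k, C in self.consensus.items():
            M = C.to_numpy()
            if not np.allclose(M, M.T):
                raise ValueError("consensus matrix must be symmetric")
            if not np.allclose(np.diag(M), 1.0):
                raise ValueError("consensus diagonal must be 1")
            if M.min() < 0 or M.max() > 1:
                raise ValueError("consensus entries must lie in [0,1]")

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_range,
            "mean_within_consensus": [self.mean_within_consensus[k] for k in self.k_range],
            "min_within_consensus": [self.min_within_consensus[k] for k in self.k_range],
            "area": [self.area[k] for k in self.k_range],
            "delta_area": [self.delta_area[k] for k in self.k_range],
            "empty_cluster_flag": [self.empty_cluster_flags[k] for k in self.k_range],
        }).set_index("k")


def _keyed_uniform(seed: int, rep: int, name: str) -> float:
    h = hashlib.blake2b(f"{seed}:{rep}:{name}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") / 2**64


def _scores_matrix(E) -> pd.DataFrame:
    if isinstance(E, EnrichmentMatrix):
        return E.scores
    if isinstance(E, pd.DataFrame):
        return E
    raise TypeError("expected an EnrichmentMatrix or a feature x sample DataFrame")


def minkowski_distances(scores: pd.DataFrame, p: float = 2.0) -> np.ndarray:
    """Sample x sample Minkowski distance over the feature columns."""
    return squareform(pdist(scores.to_numpy().T, metric="minkowski", p=p))


def consensus_cluster(
    E,
    k_range=range(2, 8),
    subsample: float = 0.8,
    reps: int = 10,
    minkowski_p: float = 2.0,
    seed: int = 0,
) -> ConsensusResult:
    """Resampled PAM consensus over candidate cluster numbers.

    For each rep a ``subsample`` fraction of samples is drawn (identity-keyed,
    see module docstring; the same subsamples are reused across k as in the
    reference consensus-clustering scheme) and PAM is run on the Minkowski
    distance restricted to the subsample.  consensus[i,j] = co-clustered
    count / co-sampled count; never co-sampled pairs get 0 and are counted in
    ``never_cosampled``.  Per-k labels come from PAM on 1 - consensus.
    """
    scores = _scores_matrix(E)
    samples = list(scores.columns)
    n = len(samples)
    k_range = [int(k) for k in k_range]
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if not (0.0 < subsample <= 1.0):
        raise ValueError("subsample must be in (0, 1]")

    D = minkowski_distances(scores, p=minkowski_p)
    m = int(np.floor(subsample * n))
    if m < max(k_range) + 1:
        raise ValueError("subsample too small for the largest k")

    subsets = []
    for rep in range(reps):
        u = np.array([_keyed_uniform(int(seed), rep, s) for s in samples])
        subsets.append(np.sort(np.argsort(u, kind="stable")[:m]))

    co_sampled = np.zeros((n, n))
    for idx in subsets:
        co_sampled[np.ix_(idx, idx)] += 1

    consensus, labels_by_k = {}, {}
    per_cluster, mean_within, min_within = {}, {}, {}
    cdfs, areas, dareas, empty_flags = {}, {}, {}, {}
    never = int((co_sampled[np.triu_indices(n, 1)] == 0).sum())
    prev_area = None
    for k in k_range:
        co_clustered = np.zeros((n, n))
        empty = 0
        for idx in subsets:
            lab, _ = pam(D[np.ix_(idx, idx)], k)
            if len(np.unique(lab)) < k:
                empty += 1
            same = lab[:, None] == lab[None, :]
            co_clustered[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
        consensus[k] = pd.DataFrame(C, index=samples, columns=samples)
        empty_flags[k] = empty > reps / 2

        lab_full, _ = pam(1.0 - C, k)
        lab_series = pd.Series(lab_full + 1, index=samples, name="cluster")
        labels_by_k[k] = lab_series

        within = []
        for c in range(1, k + 1):
            members = np.flatnonzero(lab_series.to_numpy() == c)
            if len(members) >= 2:
                block = C[np.ix_(members, members)]
                within.append(float(block[np.triu_indices(len(members), 1)].mean()))
            elif len(members) == 1:
                within.append(0.0)      # a singleton carries no stable-pair evidence
        per_cluster[k] = within
        mean_within[k] = float(np.mean(within)) if within else float("nan")
        min_within[k] = float(np.min(within)) if within else float("nan")

        upper = C[np.triu_indices(n, 1)]
        cdf = np.searchsorted(np.sort(upper), ConsensusResult.CDF_GRID,
                              side="right") / upper.size
        cdfs[k] = cdf
        area = float(np.trapezoid(cdf, ConsensusResult.CDF_GRID))
        areas[k] = area
        dareas[k] = float("inf") if prev_area is None else (area - prev_area) / prev_area
        prev_area = area

    return ConsensusResult(consensus, labels_by_k, per_cluster, mean_within,
                           min_within, cdfs, areas, dareas, never, empty_flags,
                           samples, k_range)


def select_k(
    res: ConsensusResult,
    mean_consensus_floor: float = 0.85,
    delta_area_eps: float = 0.05,
):
    """Choose the cluster number from a consensus run.

    k = the largest candidate for which every cluster's mean within-cluster
    consensus is at or above the floor (the floor applies per cluster: an
    over-split solution hides its unstable fragments inside an average) *and*
    whose relative CDF-area gain over k-1 exceeds ``delta_area_eps`` (the
    smallest candidate passes the gain test by definition).  If no candidate
    meets the floor, the argmax mean-consensus k is returned with
    ``warning=True``.  The per-k decision trace is always returned.
    """
    if len(res.k_range) < 2:
        raise ValueError("need at least 2 candidate k")
    trace = res.trace()
    eligible = [
        k for k in res.k_range
        if res.min_within_consensus[k] >= mean_consensus_floor
        and (res.delta_area[k] > delta_area_eps or k == res.k_range[0])
    ]
    if eligible:
        return max(eligible), trace, False
    best = max(res.k_range, key=lambda k: (res.mean_within_consensus[k], -k))
    return best, trace, True


# ------------------------------------------------------- silhouette --------

@dataclass
class SilhouetteReport:
    widths: pd.Series                 # per-sample silhouette width in [-1,1]
    cluster_means: pd.Series
    overall_mean: float
    moves: pd.DataFrame               # sample, iteration, from, to, accepted

    def __post_init__(self) -> None:
        w = self.widths.to_numpy()
        if (w < -1 - 1e-9).any() or (w > 1 + 1e-9).any():
            raise ValueError("silhouette widths must lie in [-1, 1]")


def silhouette_widths(D: np.ndarray, labels: np.ndarray):
    """Per-sample silhouette width, within-cluster mean a(i), and the
    b(i)-minimising neighbour cluster."""
    D = as_distance_matrix(D)
    labels = np.asarray(labels)
    n = len(labels)
    clusters = np.unique(labels)
    mean_to = np.full((n, len(clusters)), np.inf)
    sizes = {c: int((labels == c).sum()) for c in clusters}
    for ci, c in enumerate(clusters):
        members = labels == c
        tot = D[:, members].sum(axis=1)
        mean_to[:, ci] = tot / np.maximum(members.sum(), 1)
        own = members & (sizes[c] > 1)
        mean_to[own, ci] = tot[own] / (sizes[c] - 1)
    own_idx = np.searchsorted(clusters, labels)
    a = mean_to[np.arange(n), own_idx]
    b_matrix = mean_to.copy()
    b_matrix[np.arange(n), own_idx] = np.inf
    neighbour = clusters[np.argmin(b_matrix, axis=1)]
    b = b_matrix.min(axis=1)
    width = np.where(
        [sizes[c] == 1 for c in labels],
        0.0,                                   # singleton convention
        (b - a) / np.maximum(np.maximum(a, b), 1e-300),
    )
    return width, a, neighbour


def silhouette_refine(D: np.ndarray, labels, max_iter: int = 10):
    """Iteratively reassign negative-width samples to their neighbouring
    (b-minimising) cluster when the move raises their own width.

    Moves that would empty a cluster are rejected and logged.  An iteration
    that fails to raise the overall mean width is rolled back and the loop
    stops, so the overall mean silhouette is non-decreasing across
    iterations.  Returns ``(report, refined_labels)``.
    """
    D = as_distance_matrix(D)
    if isinstance(labels, pd.Series):
        index = labels.index
        lab = labels.to_numpy().copy()
    else:
        index = pd.RangeIndex(len(labels))
        lab = np.asarray(labels).copy()
    if len(np.unique(lab)) < 2:
        raise ValueError("need at least 2 clusters")

    moves = []
    width, _, _ = silhouette_widths(D, lab)
    mean_prev = width.mean()
    for it in range(max_iter):
        width, _, neighbour = silhouette_widths(D, lab)
        negatives = np.flatnonzero(width < 0)
        if negatives.size == 0:
            break
        negatives = negatives[np.argsort(width[negatives], kind="stable")]
        lab_iter_start = lab.copy()
        changed = False
        for i in negatives:
            src, dst = lab[i], neighbour[i]
            if (lab == src).sum() <= 1:
                moves.append({"sample": index[i], "iteration": it, "from": src,
                              "to": dst, "accepted": False, "reason": "would_empty"})
                continue
            trial = lab.copy()
            trial[i] = dst
            new_width, _, _ = silhouette_widths(D, trial)
            if new_width[i] > width[i]:
                lab = trial
                width = new_width
                changed = True
                moves.append({"sample": index[i], "iteration": it, "from": src,
                              "to": dst, "accepted": True, "reason": "improved"})
            else:
                moves.append({"sample": index[i], "iteration": it, "from": src,
                              "to": dst, "accepted": False, "reason": "no_gain"})
        mean_now = silhouette_widths(D, lab)[0].mean()
        if mean_now < mean_prev - 1e-12:
            lab = lab_iter_start          # roll back a mean-degrading iteration
            for m in moves:
                if m["iteration"] == it and m["accepted"]:
                    m["accepted"] = False
                    m["reason"] = "rolled_back"
            break
        mean_prev = mean_now
        if not changed:
            break

    width, _, _ = silhouette_widths(D, lab)
    widths = pd.Series(width, index=index, name="silhouette")
    cluster_means = widths.groupby(pd.Series(lab, index=index)).mean()
    report = SilhouetteReport(
        widths=widths,
        cluster_means=cluster_means,
        overall_mean=float(width.mean()),
        moves=pd.DataFrame(moves, columns=["sample", "iteration", "from", "to",
                                           "accepted", "reason"]),
    )
    refined = pd.Series(lab, index=index, name="cluster")
    return report, refined
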