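"""Weighted co-expression network over prognostic genes: soft-threshold
selection against a scale-free fit, topological overlap, average-linkage
module detection with a grey (unassigned) bucket, module eigengenes, and
gene-significance / module-membership hub selection.

The network is unsigned: adjacency = |Pearson correlation| ** beta.  The
topological overlap of genes i, j credits shared neighbours:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

with TOM_ii = 1; entries lie in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionNetwork",
    "HubGeneReport",
    "pick_soft_threshold",
    "build_tom",
    "detect_modules",
    "module_stats",
    "select_hub_genes",
    "MODULE_COLOURS",
]

# canonical module colour sequence (assigned by decreasing module size)
MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
GREY = "grey"


@dataclass
class CoexpressionNetwork:
    beta: float
    adjacency: pd.DataFrame          # gene x gene in [0,1], diagonal 1
    tom: pd.DataFrame                # gene x gene in [0,1], diagonal 1
    fit_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, M in (("adjacency", self.adjacency), ("TOM", self.tom)):
            A = M.to_numpy()
            if not np.allclose(A, A.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if A.min() < -1e-9 or A.max() > 1 + 1e-9:
                raise ValueError(f"{name} entries must lie in [0, 1]")


def _drop_constant(expr: pd.DataFrame):
    sd = expr.std(axis=1, ddof=0)
    dropped = list(expr.index[sd == 0])
    return expr.loc[sd > 0], dropped


def _scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed R^2 of log10 p(k) ~ log10 k over connectivity bins (positive
    only when the slope is negative, as a scale-free topology requires)."""
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size:
            xs.append(np.log10(members.mean()))
            ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - (slope * np.array(xs) + intercept)
    ss_tot = float(((np.array(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return (-np.sign(slope)) * r2, float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_target: float = 0.8,
):
    """Smallest power whose signed scale-free fit R^2 reaches the target
    (argmax R^2 if none does).  Returns ``(beta, fit_table)``; warns below 20
    samples; constant genes are dropped."""
    if expr.shape[1] < 20:
        warnings.warn("fewer than 20 samples: soft-threshold fit is unstable",
                      stacklevel=2)
    expr, _ = _drop_constant(expr)
    C = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(C, 0.0)
    rows = []
    for beta in powers:
        A = C ** beta
        k = A.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k)),
                     "max_k": float(k.max())})
    table = pd.DataFrame(rows).set_index("power")
    passing = table.index[table["signed_r2"] >= r2_target]
    beta = int(passing[0]) if len(passing) else int(table["signed_r2"].idxmax())
    return beta, table


def build_tom(expr: pd.DataFrame, beta: float) -> CoexpressionNetwork:
    """Unsigned adjacency |cor|^beta and its topological overlap matrix.

    Genes with zero variance (NaN correlations) are dropped.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr, _ = _drop_constant(expr)
    genes = list(expr.index)
    A = np.abs(np.corrcoef(expr.to_numpy())) ** beta
    np.fill_diagonal(A, 1.0)
    A_off = A.copy()
    np.fill_diagonal(A_off, 0.0)
    k = A_off.sum(axis=1)
    # (A_off @ A_off)_ij = sum_u a_iu a_uj with the u == i and u == j terms
    # vanishing because the diagonal of A_off is zero
    L = A_off @ A_off
    num = L + A_off
    den = np.minimum.outer(k, k) + 1.0 - A_off
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return CoexpressionNetwork(
        beta=float(beta),
        adjacency=pd.DataFrame(A, index=genes, columns=genes),
        tom=pd.DataFrame(T, index=genes, columns=genes),
    )


def detect_modules(
    net: CoexpressionNetwork,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    When ``cut_height`` is not given, the cut is chosen adaptively in two
    steps: every merge height is tried and the heights maximising the number
    of clusters of size >= ``min_module_size`` are shortlisted; among those
    the cut at the lower edge of the largest gap between consecutive merge
    heights wins (the longest-branch heuristic: module-internal merges sit
    low, background genes and the root attach after a gap).  TOM distances
    concentrate just below 1 on sparse networks, so a cut at a fixed fraction
    of the tree height is brittle; the adaptive scan is deterministic and
    recovers dense subtrees regardless of the overall distance scale.
    Clusters smaller than ``min_module_size`` go to ``grey``; surviving
    modules are named by decreasing size with the canonical colour sequence
    (ties broken by the lexicographically smallest member gene, so labels do
    not depend on gene input order).
    """
    genes = list(net.tom.index)
    d = squareform(1.0 - net.tom.to_numpy(), checks=False)
    Z = average(d)
    if cut_height is None:
        heights = np.unique(Z[:, 2])
        next_gap = np.append(np.diff(heights), 0.0)
        n_big = np.empty(len(heights), dtype=int)
        for i, h in enumerate(heights):
            counts = np.bincount(fcluster(Z, t=h, criterion="distance"))
            n_big[i] = int((counts >= min_module_size).sum())
        tied = np.flatnonzero(n_big == n_big.max())
        cut_height = float(heights[tied[np.argmax(next_gap[tied])]])
    raw = fcluster(Z, t=cut_height, criterion="distance")
    out = pd.Series(GREY, index=genes, name="module", dtype=object)
    clusters = []
    for c in np.unique(raw):
        members = [g for g, r in zip(genes, raw) if r == c]
        if len(members) >= min_module_size:
            clusters.append(members)
    clusters.sort(key=lambda ms: (-len(ms), min(ms)))
    if not clusters:
        warnings.warn("all genes assigned to grey (no module met the size floor)",
                      stacklevel=2)
    for colour, members in zip(MODULE_COLOURS, clusters):
        out.loc[members] = colour
    return out


@dataclass
class HubGeneReport:
    """Per-gene module colour, module membership (MM, correlation with the
    own-module eigengene) and gene significance (GS, correlation with each
    subtype's one-hot indicator)."""

    table: pd.DataFrame               # columns: module, MM, GS_<subtype>...
    eigengenes: pd.DataFrame          # module x sample

    def __post_init__(self) -> None:
        gs_cols = [c for c in self.table.columns if c.startswith("GS_")]
        vals = self.table[gs_cols + ["MM"]].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("|GS| and |MM| must be <= 1")


def _eigengene(block: np.ndarray) -> np.ndarray:
    """First principal component over samples of the standardised module
    block (genes x samples), sign-anchored to a positive mean gene loading."""
    z = (block - block.mean(axis=1, keepdims=True)) / np.maximum(
        block.std(axis=1, keepdims=True), 1e-300)
    if z.shape[0] == 1:
        return z[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    if u[:, 0].mean() < 0:
        e = -e
    return e


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    zx = (X - X.mean(axis=1, keepdims=True)) / np.maximum(
        X.std(axis=1, keepdims=True), 1e-300)
    sy = y.std()
    if sy == 0:
        return np.full(X.shape[0], np.nan)
    zy = (y - y.mean()) / sy
    return np.clip(zx @ zy / X.shape[1], -1.0, 1.0)


def module_stats(
    expr: pd.DataFrame,
    modules: pd.Series,
    subtype_labels: pd.Series,
) -> HubGeneReport:
    """GS and MM tables for every gene.

    The eigengene of each non-grey module is the first PC of its standardised
    expression; MM is each gene's correlation with its own module's eigengene
    (NaN for grey genes); GS_<s> is the gene's correlation with the one-hot
    indicator of subtype s.
    """
    modules = modules.reindex(expr.index)
    labels = subtype_labels.reindex(expr.columns)
    non_grey = [m for m in modules.unique() if m != GREY]
    if not non_grey:
        raise ValueError("no non-grey module present")
    X = expr.to_numpy(dtype=float)

    eig = {}
    for m in sorted(non_grey):
        block = X[(modules == m).to_numpy()]
        eig[m] = _eigengene(block)
    eigengenes = pd.DataFrame(eig, index=expr.columns).T

    mm = np.full(len(expr.index), np.nan)
    for m in non_grey:
        members = (modules == m).to_numpy()
        mm[members] = _pearson_rows(X[members], eig[m])
    table = pd.DataFrame({"module": modules.to_numpy(), "MM": mm}, index=expr.index)
    for s in sorted(labels.unique()):
        indicator = (labels == s).to_numpy(dtype=float)
        table[f"GS_{s}"] = _pearson_rows(X, indicator)
    return HubGeneReport(table=table, eigengenes=eigengenes)


def select_hub_genes(
    report: HubGeneReport,
    gs_thresh: float = 0.3,
    mm_thresh: float = 0.8,
    top_n: int = 10,
) -> dict:
    """Per-subtype hub lists: genes with |GS| > gs_thresh and |MM| >
    mm_thresh, ranked by |GS| descending (ties by |MM| then name), truncated
    at top_n.  A subtype with fewer qualifying genes returns them all with a
    warning."""
    table = report.table
    gs_cols = [c for c in table.columns if c.startswith("GS_")]
    hubs = {}
    for col in gs_cols:
        subtype = col[3:]
        q = table[(table[col].abs() > gs_thresh) & (table["MM"].abs() > mm_thresh)
                  & (table["module"] != GREY)]
        ranked = q.assign(_gs=q[col].abs(), _mm=q["MM"].abs()).sort_values(
            ["_gs", "_mm"], ascending=False, kind="stable"
        )
        ranked = ranked.iloc[np.lexsort((
            ranked.index.to_numpy(), -ranked["_mm"].to_numpy(), -ranked["_gs"].to_numpy()
        ))]
        if len(ranked) < top_n:
            warnings.warn(f"subtype {subtype}: only {len(ranked)} hub genes qualify",
                          stacklevel=2)
        hubs[subtype] = list(ranked.index[:top_n])
    return hubs
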