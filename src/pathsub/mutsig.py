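"""Mutational signatures: 96-trinucleotide-context catalogs from MAF-lite
input, de novo extraction by KL-divergence NMF, nearest-reference matching by
cosine similarity, and exposure refitting with multinomial bootstrap
stability.

Single-base substitutions are collapsed to the pyrimidine frame: a purine
reference (A/G) is reverse-complemented together with both flanking bases, so
only the six substitution types C>A, C>G, C>T, T>A, T>C, T>G remain; crossed
with the 4 x 4 flank combinations this gives the fixed 96-class catalog row
order used throughout (substitution-major, then 5' and 3' flank
alphabetically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from ._utils import rng_from_seed, spawn_seeds

__all__ = [
    "SUBSTITUTION_TYPES",
    "CONTEXT_CLASSES",
    "MutationCatalog",
    "ContextMatrix",
    "SignatureSet",
    "RefittingResult",
    "parse_context_class",
    "read_maf",
    "build_context_matrix",
    "extract_signatures",
    "match_reference",
    "refit_exposures",
    "signature_expression_screen",
    "tmb",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _enumerate_substitution_types() -> list[str]:
    """The strand-collapsed (pyrimidine-reference) substitution types."""
    return [f"{ref}>{alt}" for ref in ("C", "T") for alt in _BASES if alt != ref]


def _enumerate_context_classes() -> list[str]:
    """Fixed row order: substitution-major, flanks alphabetical."""
    return [
        f"{five}[{sub}]{three}"
        for sub in _enumerate_substitution_types()
        for five in _BASES
        for three in _BASES
    ]


SUBSTITUTION_TYPES = _enumerate_substitution_types()
CONTEXT_CLASSES = _enumerate_context_classes()
_CLASS_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES)}


def parse_context_class(cls: str):
    """'A[C>T]G' -> ('A', 'C', 'T', 'G')."""
    return cls[0], cls[2], cls[4], cls[6]


REQUIRED_MAF_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "variant_type",
                        "ref_context"]


@dataclass
class MutationCatalog:
    """Somatic variant records with explicit trinucleotide contexts.

    ``records`` keeps all accepted rows with an ``is_snv`` flag (doublets and
    indels pass through flagged, not dropped); ``rejected`` counts rows
    removed per reason (malformed context, context/ref mismatch, ambiguous
    base).
    """

    records: pd.DataFrame
    rejected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        snv = self.records[self.records["is_snv"]]
        if len(snv):
            if (snv["ref"] == snv["alt"]).any():
                raise ValueError("SNV records must have ref != alt")
            mid = snv["ref_context"].str[1]
            if (mid != snv["ref"]).any():
                raise ValueError("context middle base must equal ref")


def read_maf(path) -> MutationCatalog:
    """Read a MAF-lite TSV (columns: sample, chrom, pos, ref, alt,
    variant_type, ref_context).

    SNV rows (variant_type SNP/SNV with single-base ref and alt) are
    validated: the context must be three bases from {ACGT} whose middle base
    equals ref.  Malformed rows are rejected individually and counted;
    non-SNV rows are retained flagged.  A missing required column rejects the
    whole file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return _catalog_from_frame(df)


def _catalog_from_frame(df: pd.DataFrame) -> MutationCatalog:
    df = df.copy()
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    df["ref_context"] = df["ref_context"].str.upper()
    is_snv = (df["variant_type"].str.upper().isin(["SNP", "SNV"])
              & (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1))
    rejected = {"bad_context": 0, "context_ref_mismatch": 0, "ambiguous_base": 0,
                "ref_equals_alt": 0}
    keep = np.ones(len(df), dtype=bool)
    ctx = df["ref_context"].fillna("")
    bad_len = is_snv & (ctx.str.len() != 3)
    ambiguous = is_snv & ~bad_len & ~ctx.str.fullmatch("[ACGT]{3}").fillna(False)
    mismatch = is_snv & ~bad_len & ~ambiguous & (ctx.str[1] != df["ref"])
    same = is_snv & (df["ref"] == df["alt"])
    rejected["bad_context"] = int(bad_len.sum())
    rejected["ambiguous_base"] = int(ambiguous.sum())
    rejected["context_ref_mismatch"] = int((mismatch & ~same).sum())
    rejected["ref_equals_alt"] = int(same.sum())
    keep &= ~(bad_len | ambiguous | mismatch | same).to_numpy()
    out = df.loc[keep].reset_index(drop=True)
    out["is_snv"] = is_snv.loc[keep].to_numpy()
    out["pos"] = pd.to_numeric(out["pos"])
    return MutationCatalog(out, {k: v for k, v in rejected.items() if v})


@dataclass
class ContextMatrix:
    """96 x samples integer counts in the fixed pyrimidine-frame row order."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.index) != CONTEXT_CLASSES:
            raise ValueError("context matrix must use the fixed 96-class row order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("context counts must be non-negative")

    def to_numpy(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


def _collapse_to_pyrimidine(five: str, ref: str, alt: str, three: str):
    if ref in ("A", "G"):
        five, ref, alt, three = (_COMPLEMENT[three], _COMPLEMENT[ref],
                                 _COMPLEMENT[alt], _COMPLEMENT[five])
    return f"{five}[{ref}>{alt}]{three}"


def build_context_matrix(cat: MutationCatalog) -> ContextMatrix:
    """Accumulate strand-collapsed trinucleotide counts per sample.

    Purine-reference SNVs are reverse-complemented (substitution and both
    flanks) into the pyrimidine frame.  Column sums equal each sample's valid
    SNV count by construction.
    """
    snv = cat.records[cat.records["is_snv"]]
    if snv.empty:
        raise ValueError("catalog contains no valid SNVs")
    samples = sorted(snv["sample"].unique())
    counts = pd.DataFrame(0, index=CONTEXT_CLASSES, columns=samples, dtype=int)
    classes = [
        _collapse_to_pyrimidine(ctx[0], ref, alt, ctx[2])
        for ctx, ref, alt in zip(snv["ref_context"], snv["ref"], snv["alt"])
    ]
    tab = pd.crosstab(np.asarray(classes), snv["sample"].to_numpy())
    counts.loc[tab.index, tab.columns] = tab
    return ContextMatrix(counts)


# ----------------------------------------------------------- NMF -----------

@dataclass
class SignatureSet:
    """One NMF factorisation: column-stochastic profiles W (96 x r) and
    non-negative exposures H (r x samples), with the KL objective trace of the
    best restart."""

    W: pd.DataFrame
    H: pd.DataFrame
    objective_trace: np.ndarray
    converged: bool
    restarts: int
    seed: int
    cophenetic: float = float("nan")

    def __post_init__(self) -> None:
        if not np.allclose(self.W.sum(axis=0).to_numpy(), 1.0, atol=1e-9):
            raise ValueError("signature profiles must be column-stochastic (tol 1e-9)")
        if (self.H.to_numpy() < 0).any():
            raise ValueError("exposures must be non-negative")
        d = np.diff(self.objective_trace)
        if (d > 1e-6 * np.maximum(self.objective_trace[:-1], 1.0)).any():
            raise ValueError("KL objective must be non-increasing over iterations")

    @property
    def rank(self) -> int:
        return self.W.shape[1]


def _kl_divergence(V, WH):
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _nmf_kl(V: np.ndarray, r: int, rng: np.random.Generator,
            max_iter: int, tol: float):
    """Multiplicative-update NMF under generalized KL divergence."""
    eps = 1e-12
    scale = np.sqrt(V.mean() / r)
    W = rng.uniform(0.5, 1.5, size=(V.shape[0], r)) * scale
    H = rng.uniform(0.5, 1.5, size=(r, V.shape[1])) * scale
    trace = [ _kl_divergence(V, W @ H + eps) ]
    converged = False
    for _ in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(V, W @ H + eps)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    colsum = np.maximum(W.sum(axis=0), eps)
    W = W / colsum
    H = H * colsum[:, None]
    return W, H, np.array(trace), converged


def _rank1_kl(V: np.ndarray):
    """Closed-form rank-1 KL-NMF fixed point: profile = normalised row
    marginal, exposures = column sums."""
    w = V.sum(axis=1) / V.sum()
    h = V.sum(axis=0)
    return w[:, None], h[None, :]


def extract_signatures(
    M: ContextMatrix,
    k_range=range(2, 7),
    restarts: int = 30,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    cophenetic_delta: float = 0.02,
):
    """De novo signature extraction over a range of ranks.

    Per rank the best of ``restarts`` seeded multiplicative-update runs (by
    final KL objective) is retained; a cophenetic coefficient is computed from
    the restart-consensus of dominant-signature co-assignment of samples
    (average-linkage tree vs consensus distances).  The returned rank is the
    last one before the first cophenetic drop larger than
    ``cophenetic_delta`` (argmax cophenetic if no such drop).  Returns
    ``(sets_by_k, chosen_rank, diagnostics)``.
    """
    V = M.to_numpy()
    n = V.shape[1]
    if (V.sum(axis=0) <= 0).any():
        raise ValueError("every sample column must have a positive mutation count")
    k_range = [int(k) for k in k_range]
    if min(k_range) < 1 or max(k_range) > min(96, n) - 1:
        raise ValueError("k_range must lie within [1, min(96, samples) - 1]")

    sets: dict[int, SignatureSet] = {}
    diag_rows = []
    for k in k_range:
        if k == 1:
            W, H = _rank1_kl(V)
            trace = np.array([_kl_divergence(V, W @ H + 1e-12)])
            best = (W, H, trace, True)
            coph = 1.0
        else:
            best = None
            assignments = []
            for rs in spawn_seeds(int(seed) + k, restarts):
                rng = rng_from_seed(rs)
                W, H, trace, conv = _nmf_kl(V, k, rng, max_iter, tol)
                assignments.append(np.argmax(H, axis=0))
                if best is None or trace[-1] < best[2][-1]:
                    best = (W, H, trace, conv)
            A = np.array(assignments)
            C = (A[:, :, None] == A[:, None, :]).mean(axis=0)
            dist = squareform(1.0 - C, checks=False)
            if np.allclose(dist, 0):
                coph = 1.0
            else:
                coph = float(cophenet(average(dist), dist)[0])
                if np.isnan(coph):
                    coph = 1.0
        W, H, trace, conv = best
        sets[k] = SignatureSet(
            W=pd.DataFrame(W, index=CONTEXT_CLASSES,
                           columns=[f"S{j+1}" for j in range(k)]),
            H=pd.DataFrame(H, index=[f"S{j+1}" for j in range(k)],
                           columns=M.counts.columns),
            objective_trace=trace,
            converged=conv,
            restarts=restarts if k > 1 else 1,
            seed=int(seed),
            cophenetic=coph,
        )
        diag_rows.append({"k": k, "objective": float(trace[-1]),
                          "cophenetic": coph, "converged": conv})

    diagnostics = pd.DataFrame(diag_rows).set_index("k")
    coph_vals = diagnostics["cophenetic"]
    chosen = k_range[-1]
    dropped = False
    for a, b in zip(k_range[:-1], k_range[1:]):
        if coph_vals[a] - coph_vals[b] > cophenetic_delta:
            chosen = a
            dropped = True
            break
    if not dropped:
        chosen = int(coph_vals.idxmax())
    return sets, chosen, diagnostics


def match_reference(W, ref: pd.DataFrame, one_to_one: bool = False) -> pd.DataFrame:
    """Cosine-similarity match of extracted signatures to a reference
    catalogue in the same fixed 96-row order.

    Default is an independent argmax per extracted signature; with
    ``one_to_one`` a Hungarian (bipartite) assignment maximising total cosine
    is used instead.
    """
    Wdf = W.W if isinstance(W, SignatureSet) else W
    if list(ref.index) != list(Wdf.index):
        raise ValueError(
            "reference rows must match the fixed 96-class order; reindex the "
            "reference with mutsig.CONTEXT_CLASSES before matching"
        )
    A = Wdf.to_numpy(dtype=float)
    B = ref.to_numpy(dtype=float)
    A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    B = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    S = A.T @ B                                        # r x m cosine matrix
    if one_to_one:
        from scipy.optimize import linear_sum_assignment
        rows, cols = linear_sum_assignment(-S)
        pairs = dict(zip(rows, cols))
        idx = [pairs[i] for i in range(S.shape[0])]
    else:
        idx = np.argmax(S, axis=1)
    return pd.DataFrame({
        "signature": Wdf.columns,
        "best_match": [ref.columns[j] for j in idx],
        "cosine": [float(S[i, j]) for i, j in enumerate(idx)],
    }).set_index("signature")


# ------------------------------------------------------- refitting ---------

@dataclass
class RefittingResult:
    """NNLS point exposures plus multinomial-bootstrap replicates.

    ``point``/``point_fraction``: r x samples; ``replicates``:
    n_boot x r x samples (fractions); ``stability``: per-signature,
    per-sample SD and the fraction of replicates with a positive exposure.
    """

    point: pd.DataFrame
    point_fraction: pd.DataFrame
    replicates: np.ndarray
    stability_sd: pd.DataFrame
    positivity: pd.DataFrame
    zero_mutation_samples: list[str]

    def __post_init__(self) -> None:
        if (self.point.to_numpy() < -1e-12).any():
            raise ValueError("exposures must be non-negative")


def refit_exposures(
    M: ContextMatrix,
    ref_signatures: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
) -> RefittingResult:
    """Refit per-sample exposures to fixed reference profiles.

    Point estimates by non-negative least squares on the 96-context counts;
    each bootstrap replicate resamples every sample's mutations multinomially
    at its observed total (probabilities = observed spectrum) and refits.
    Samples with zero mutations get all-zero exposures and are flagged.
    """
    if list(ref_signatures.index) != CONTEXT_CLASSES:
        raise ValueError("reference rows must use the fixed 96-class order")
    P = ref_signatures.to_numpy(dtype=float)
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("reference profiles must be column-stochastic")
    V = M.to_numpy()
    samples = list(M.counts.columns)
    rng = rng_from_seed(seed)

    def _fit(v):
        if v.sum() <= 0:
            return np.zeros(P.shape[1])
        return optimize.nnls(P, v)[0]

    point = np.column_stack([_fit(V[:, j]) for j in range(V.shape[1])])
    totals = point.sum(axis=0)
    frac = np.where(totals > 0, point / np.maximum(totals, 1e-300), 0.0)

    reps = np.zeros((n_boot, P.shape[1], len(samples)))
    for b in range(n_boot):
        for j in range(len(samples)):
            tot = int(V[:, j].sum())
            if tot == 0:
                continue
            v = rng.multinomial(tot, V[:, j] / V[:, j].sum()).astype(float)
            e = _fit(v)
            s = e.sum()
            reps[b, :, j] = e / s if s > 0 else 0.0

    sig_idx = list(ref_signatures.columns)
    zero = [s for j, s in enumerate(samples) if V[:, j].sum() == 0]
    return RefittingResult(
        point=pd.DataFrame(point, index=sig_idx, columns=samples),
        point_fraction=pd.DataFrame(frac, index=sig_idx, columns=samples),
        replicates=reps,
        stability_sd=pd.DataFrame(reps.std(axis=0), index=sig_idx, columns=samples),
        positivity=pd.DataFrame((reps > 0).mean(axis=0), index=sig_idx, columns=samples),
        zero_mutation_samples=zero,
    )


def signature_expression_screen(
    H: pd.DataFrame,
    expr: pd.DataFrame,
    r_thresh: float = 0.2,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen of genes against per-sample signature fractions.

    Positive screen: a (gene, signature) row is flagged when r > r_thresh and
    p < p_thresh.  Constant genes are skipped and logged in the ``skipped``
    attribute of the result.
    """
    shared = [s for s in expr.columns if s in H.columns]
    if len(shared) < 10:
        raise ValueError("need >= 10 shared samples")
    X = expr[shared].to_numpy(dtype=float)
    E = H[shared].to_numpy(dtype=float)
    const = X.std(axis=1) == 0
    genes = expr.index[~const]
    X = X[~const]
    n = len(shared)
    zx = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    ze = (E - E.mean(axis=1, keepdims=True)) / np.maximum(E.std(axis=1, keepdims=True), 1e-300)
    R = (zx @ ze.T) / n                              # genes x signatures
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1 - R**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    rows = []
    for gi, g in enumerate(genes):
        for si, s in enumerate(H.index):
            rows.append({"gene": g, "signature": s, "r": R[gi, si], "p": p[gi, si],
                         "flagged": (R[gi, si] > r_thresh) and (p[gi, si] < p_thresh)})
    out = pd.DataFrame(rows).sort_values(["signature", "p"], kind="stable").reset_index(drop=True)
    out.attrs["skipped"] = list(expr.index[const])
    return out


def tmb(cat: MutationCatalog) -> pd.DataFrame:
    """Per-sample tumour mutational burden: total somatic variant count and
    the SNV-only count (raw counts; no capture-size normalisation)."""
    total = cat.records.groupby("sample").size()
    snv = cat.records[cat.records["is_snv"]].groupby("sample").size()
    out = pd.DataFrame({"total": total, "snv": snv}).fillna(0).astype(int)
    out.index.name = "sample"
    return out.sort_index()
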