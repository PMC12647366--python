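"""Downstream statistical screens: one-vs-rest differential expression,
multi-group ANOVA, pairwise mutation co-occurrence / exclusivity, multi-omic
correlation screens, Kaplan-Meier / log-rank comparisons, univariate Cox
regression and maximally selected survival cutpoints.

Screen thresholds default to raw p values (the convention of the analyses
they mirror); Benjamini-Hochberg adjusted p values are always computed and
reported alongside so FDR control is an opt-in reading of the same table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import rng_from_seed

__all__ = [
    "SurvivalTable",
    "deg_one_vs_rest",
    "anova_screen",
    "fisher_pair_patterns",
    "correlation_screen",
    "survival_compare",
    "cox_univariate",
    "maxstat_cutpoint",
    "logrank_two_group",
]


def _as_survival(surv: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"}.issubset(surv.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0/1")
    return surv


SurvivalTable = pd.DataFrame    # sample-indexed frame with time/event columns


# ------------------------------------------------- differential expression -

def deg_one_vs_rest(
    expr: pd.DataFrame,
    labels: pd.Series,
    p_thresh: float = 0.05,
    lfc_thresh: float = 2.0,
) -> dict:
    """Per-subtype one-vs-rest differential expression.

    Welch t on log2(x + 1) per gene; log2 fold change is computed on group
    means, log2(mean_subtype + 1) - log2(mean_rest + 1).  The gene list is
    thresholded on raw p and |log2FC| (BH-adjusted p reported in the table).
    Subtypes with fewer than 3 samples are skipped with a warning.
    """
    labels = labels.reindex(expr.columns)
    X = expr.to_numpy(dtype=float)
    logX = np.log2(X + 1.0)
    out = {}
    for s in sorted(labels.unique()):
        members = (labels == s).to_numpy()
        if members.sum() < 3 or (~members).sum() < 3:
            warnings.warn(f"subtype {s}: fewer than 3 samples on one side, skipped",
                          stacklevel=2)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(logX[:, members], logX[:, ~members],
                                   axis=1, equal_var=False)
        lfc = np.log2(X[:, members].mean(axis=1) + 1.0) - np.log2(
            X[:, ~members].mean(axis=1) + 1.0)
        ok = np.isfinite(p)
        p_adj = np.full_like(p, np.nan)
        if ok.any():
            p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        table = pd.DataFrame({"t": t, "p": p, "p_adj": p_adj, "log2fc": lfc},
                             index=expr.index)
        table["flagged"] = (table["p"] < p_thresh) & (table["log2fc"].abs() > lfc_thresh)
        out[s] = table.sort_values("p", kind="stable")
    return out


def anova_screen(matrix: pd.DataFrame, labels: pd.Series, p_thresh: float = 0.05
                 ) -> pd.DataFrame:
    """One-way ANOVA per feature across k groups (k = 2 reduces to the
    pooled-variance t test, F = t^2).

    Features with zero within-group variance are flagged degenerate: p = 0
    when the group means differ (the F statistic diverges), NaN when the
    feature is globally constant.
    """
    labels = labels.reindex(matrix.columns)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("ANOVA screen needs >= 2 groups")
    X = matrix.to_numpy(dtype=float)
    blocks = [X[:, (labels == g).to_numpy()] for g in groups]
    within = sum(((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for b in blocks)
    grand = X.mean(axis=1)
    between = sum(b.shape[1] * (b.mean(axis=1) - grand) ** 2 for b in blocks)
    df_b, df_w = len(groups) - 1, X.shape[1] - len(groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (between / df_b) / (within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    degenerate = within == 0
    p = np.where(degenerate & (between > 0), 0.0, p)
    p = np.where(degenerate & (between == 0), np.nan, p)
    out = pd.DataFrame({"F": F, "p": p, "degenerate": degenerate}, index=matrix.index)
    out["flagged"] = out["p"] < p_thresh
    return out


# -------------------------------------------------------- mutation pairs ---

@dataclass
class PairPatternResult:
    gene_a: str
    gene_b: str
    both: int
    only_a: int
    only_b: int
    neither: int
    odds_ratio: float
    direction: str                    # "co-occurrence" or "exclusivity"
    p: float
    p_adj: float = float("nan")


def fisher_pair_patterns(binary_matrix: pd.DataFrame, p_thresh: float = 0.05
                         ) -> pd.DataFrame:
    """Two-sided Fisher exact test on mutation co-status for every gene pair.

    Direction is co-occurrence when the odds ratio exceeds 1, exclusivity
    otherwise.  Genes mutated in none or all samples are uninformative; their
    pairs are skipped and listed in the result's ``skipped`` attribute.
    BH-adjusted p values are reported alongside the raw ones.
    """
    if binary_matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    B = binary_matrix.to_numpy(dtype=bool)
    genes = list(binary_matrix.index)
    n = B.shape[1]
    informative = (B.sum(axis=1) > 0) & (B.sum(axis=1) < n)
    skipped = [g for g, ok in zip(genes, informative) if not ok]
    rows = []
    idx = np.flatnonzero(informative)
    for ii, gi in enumerate(idx):
        for gj in idx[ii + 1:]:
            a = int((B[gi] & B[gj]).sum())
            b = int((B[gi] & ~B[gj]).sum())
            c = int((~B[gi] & B[gj]).sum())
            d = n - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({
                "gene_a": genes[gi], "gene_b": genes[gj],
                "both": a, "only_a": b, "only_b": c, "neither": d,
                "odds_ratio": odds,
                "direction": "co-occurrence" if odds > 1 else "exclusivity",
                "p": p,
            })
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "both", "only_a",
                                      "only_b", "neither", "odds_ratio",
                                      "direction", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["flagged"] = out["p"] < p_thresh
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


# ------------------------------------------------------- correlations ------

def correlation_screen(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    pairing: str = "matched",
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
    sign: str = "positive",
) -> pd.DataFrame:
    """Pearson correlation screen between two feature x sample matrices.

    ``pairing='matched'`` correlates identically named features;
    ``pairing='all'`` crosses every X feature with every Y feature.  Rows are
    flagged when p < p_thresh and r > r_thresh (``sign='positive'``) or
    |r| > r_thresh (``sign='absolute'``).  Constant features are skipped and
    listed in the ``skipped`` attribute.
    """
    if sign not in ("positive", "absolute"):
        raise ValueError("sign must be 'positive' or 'absolute'")
    shared = [s for s in X.columns if s in set(Y.columns)]
    if len(shared) < 10:
        raise ValueError("need >= 10 shared samples")
    Xs, Ys = X[shared], Y[shared]
    n = len(shared)
    skipped = []

    def _z(M):
        A = M.to_numpy(dtype=float)
        sd = A.std(axis=1)
        const = sd == 0
        skipped.extend(list(M.index[const]))
        A = A[~const]
        return (A - A.mean(axis=1, keepdims=True)) / sd[~const][:, None], M.index[~const]

    zx, xi = _z(Xs)
    zy, yi = _z(Ys)
    if pairing == "matched":
        common = [f for f in xi if f in set(yi)]
        zx = zx[[list(xi).index(f) for f in common]]
        zy = zy[[list(yi).index(f) for f in common]]
        r = np.clip((zx * zy).sum(axis=1) / n, -1, 1)
        pairs = pd.DataFrame({"feature_x": common, "feature_y": common, "r": r})
    elif pairing == "all":
        R = np.clip(zx @ zy.T / n, -1, 1)
        fx, fy = np.meshgrid(np.arange(len(xi)), np.arange(len(yi)), indexing="ij")
        pairs = pd.DataFrame({"feature_x": np.asarray(xi)[fx.ravel()],
                              "feature_y": np.asarray(yi)[fy.ravel()],
                              "r": R.ravel()})
    else:
        raise ValueError("pairing must be 'matched' or 'all'")
    r = pairs["r"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    pairs["p"] = 2 * stats.t.sf(np.abs(t), df=n - 2)
    if len(pairs):
        pairs["p_adj"] = multipletests(pairs["p"], method="fdr_bh")[1]
    mag = r if sign == "positive" else np.abs(r)
    pairs["flagged"] = (mag > r_thresh) & (pairs["p"] < p_thresh)
    pairs.attrs["skipped"] = skipped
    return pairs


# ----------------------------------------------------------- survival ------

def survival_compare(surv: SurvivalTable, groups: pd.Series):
    """Kaplan-Meier curves per group and the k-group log-rank test.

    Returns a dict with per-group survival functions, median survival
    (NaN = not reached), the log-rank chi-square / p, and a warning list of
    groups with zero events.
    """
    surv = _as_survival(surv)
    groups = groups.reindex(surv.index)
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    curves, medians, warnings_out = {}, {}, []
    for g in sorted(groups.unique()):
        sub = surv[groups == g]
        if sub["event"].sum() == 0:
            warnings_out.append(f"group {g} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
        med = kmf.median_survival_time_
        medians[g] = float("nan") if np.isinf(med) else float(med)
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return {
        "curves": curves,
        "median_survival": medians,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "warnings": warnings_out,
    }


def cox_univariate(surv: SurvivalTable, covariate: pd.Series, alpha: float = 0.05):
    """Univariate Cox proportional-hazards fit (Newton on the partial
    likelihood, Breslow tie handling).

    Returns a dict with beta, HR = exp(beta), the Wald (1 - alpha) CI for the
    HR, the Wald p, and the score chi-square (which reproduces the two-group
    log-rank statistic for a binary covariate).  A constant covariate is
    rejected for lack of variation.
    """
    surv = _as_survival(surv)
    x = covariate.reindex(surv.index).to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate dropped: no variation")
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])
    # risk-set index of each unique event time in the ascending time order
    risk_start = np.searchsorted(t, event_times, side="left")
    d_per = np.array([e[(t == et)].sum() for et in event_times])
    xsum_d = np.array([x[(t == et) & (e == 1)].sum() for et in event_times])

    def derivs(beta):
        w = np.exp(beta * x)
        # suffix sums: s_k(et) = sum_{t_i >= et} w_i x_i^k
        c0 = np.concatenate([np.cumsum((w)[::-1])[::-1], [0.0]])
        c1 = np.concatenate([np.cumsum((w * x)[::-1])[::-1], [0.0]])
        c2 = np.concatenate([np.cumsum((w * x * x)[::-1])[::-1], [0.0]])
        s0, s1, s2 = c0[risk_start], c1[risk_start], c2[risk_start]
        U = float(xsum_d.sum() - (d_per * s1 / s0).sum())
        H = float((d_per * (s2 / s0 - (s1 / s0) ** 2)).sum())
        return U, H

    U0, H0 = derivs(0.0)
    score_chi2 = U0**2 / H0 if H0 > 0 else float("nan")
    beta = 0.0
    for _ in range(50):
        U, H = derivs(beta)
        if H <= 0:
            break
        step = U / H
        beta += step
        if abs(step) < 1e-10:
            break
    _, H = derivs(beta)
    se = 1.0 / np.sqrt(H) if H > 0 else float("inf")
    z = beta / se if se > 0 else 0.0
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return {
        "beta": float(beta),
        "hr": float(np.exp(beta)),
        "se": float(se),
        "ci_lower": float(np.exp(beta - zcrit * se)),
        "ci_upper": float(np.exp(beta + zcrit * se)),
        "p": float(2 * stats.norm.sf(abs(z))),
        "score_chi2": float(score_chi2),
    }


def logrank_two_group(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Two-group log-rank chi-square (1 df), vectorised over event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order]
    n = len(time)
    uniq, start = np.unique(time, return_index=True)
    # at-risk counts just before each unique time
    n_at = n - start
    cum_g = np.concatenate([[0], np.cumsum(group)])
    n1_at = group.sum() - cum_g[start]
    d = np.add.reduceat(event, start)
    d1 = np.add.reduceat(event * group, start)
    has_event = d > 0
    n_at, n1_at, d, d1 = n_at[has_event], n1_at[has_event], d[has_event], d1[has_event]
    if d.size == 0:
        return 0.0
    frac = n1_at / n_at
    o_minus_e = (d1 - d * frac).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(n_at > 1, d * frac * (1 - frac) * (n_at - d) / (n_at - 1), 0.0).sum()
    return float(o_minus_e**2 / v) if v > 0 else 0.0


def maxstat_cutpoint(
    surv: SurvivalTable,
    score: pd.Series,
    min_group_frac: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Maximally selected log-rank cutpoint on a continuous score.

    Scans the midpoints between consecutive distinct score values, keeping
    both groups at >= min_group_frac of the cohort, and returns the threshold
    maximising the two-group log-rank chi-square, with the full scan trace, a
    permutation p (scores permuted against survival, which accounts for the
    selection of the maximum) and the naive single-test chi-square p (which is
    anti-conservative and reported only for reference).
    """
    surv = _as_survival(surv)
    s = score.reindex(surv.index).to_numpy(dtype=float)
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    n = len(s)
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("score must have >= 2 distinct values")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    min_count = max(1, int(np.ceil(min_group_frac * n)))
    candidates = [c for c in mids
                  if min_count <= (s > c).sum() <= n - min_count]
    if not candidates:
        raise ValueError("no cutpoint satisfies the group-size bound")

    def scan(scores):
        return np.array([logrank_two_group(t, e, scores > c) for c in candidates])

    chis = scan(s)
    best = int(np.argmax(chis))
    rng = rng_from_seed(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(s)
        if scan(perm).max() >= chis[best]:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return {
        "cutpoint": float(candidates[best]),
        "chi2": float(chis[best]),
        "high_group": pd.Series(s > candidates[best], index=surv.index, name="high"),
        "scan": pd.DataFrame({"cutpoint": candidates, "chi2": chis}),
        "p_permutation": float(p_perm),
        "p_naive": float(stats.chi2.sf(chis[best], df=1)),
        "n_perm": n_perm,
    }
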