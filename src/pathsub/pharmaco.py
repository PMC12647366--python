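"""Drug-sensitivity stratification by subtype and mutational-signature
status, and two-class immunophenotyping from cell-type score matrices.

The AUC convention follows the GDSC-style default used throughout: AUC above
the threshold marks a *sensitive* (cell line, drug) experiment.  Because the
direction of that convention varies across database releases it is an
explicit flag, and a warning announces the direction in effect on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import consensus_cluster

__all__ = [
    "DrugResponseTable",
    "DrugStratification",
    "validate_drug_table",
    "stratify_drugs",
    "sbs_drug_match",
    "immunophenotype",
]

REQUIRED_DRUG_COLUMNS = ["cell_line", "subtype", "drug", "targets", "ic50", "auc"]

DrugResponseTable = pd.DataFrame


def validate_drug_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_DRUG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"drug table missing column(s): {', '.join(missing)}")
    if ((table["auc"] < 0) | (table["auc"] > 1)).any():
        raise ValueError("AUC values must lie in [0, 1]")
    if table.duplicated(["cell_line", "drug"]).any():
        raise ValueError("(cell line, drug) pairs must be unique per screen")
    return table


@dataclass
class DrugStratification:
    sensitive_rows: pd.DataFrame
    per_subtype: dict[str, set]
    universal: set
    specific: dict[str, set]
    shared_not_universal: set
    excluded_subtypes: list = field(default_factory=list)
    trace: pd.DataFrame | None = None

    def all_sensitive(self) -> set:
        return set().union(*self.per_subtype.values()) if self.per_subtype else set()


def stratify_drugs(
    table: DrugResponseTable,
    auc_threshold: float = 0.7,
    sensitive_above: bool = True,
    min_fraction: float | None = None,
) -> DrugStratification:
    """Partition sensitive drugs into universal / subtype-specific / shared.

    Rows with AUC above the threshold (below, if ``sensitive_above=False``)
    are sensitive.  A drug belongs to a subtype's set when at least one line
    of that subtype is sensitive (or at least ``min_fraction`` of its lines,
    when given).  universal = intersection over subtypes with >= 1 line;
    specific(s) = set(s) minus the union of the others; the remaining
    sensitive drugs are shared-but-not-universal.  The three blocks are
    disjoint and cover all sensitive drugs.
    """
    table = validate_drug_table(table)
    direction = "AUC > threshold => sensitive" if sensitive_above else \
        "AUC < threshold => sensitive"
    warnings.warn(f"drug-sensitivity convention in effect: {direction} "
                  f"(threshold {auc_threshold})", stacklevel=2)
    sens = table[table["auc"] > auc_threshold] if sensitive_above else \
        table[table["auc"] < auc_threshold]

    per_subtype: dict[str, set] = {}
    excluded = []
    for s in sorted(table["subtype"].dropna().unique()):
        lines = table[table["subtype"] == s]["cell_line"].unique()
        if len(lines) == 0:
            excluded.append(s)
            continue
        rows = sens[sens["subtype"] == s]
        if min_fraction is None:
            per_subtype[s] = set(rows["drug"].unique())
        else:
            n_lines = len(lines)
            frac = rows.groupby("drug")["cell_line"].nunique() / n_lines
            per_subtype[s] = set(frac.index[frac >= min_fraction])
    if not per_subtype:
        raise ValueError("no subtype with cell lines present")

    universal = set.intersection(*per_subtype.values())
    specific = {
        s: per_subtype[s] - set().union(*(per_subtype[o] for o in per_subtype if o != s))
        for s in per_subtype
    }
    all_sens = set().union(*per_subtype.values())
    shared = all_sens - universal - set().union(*specific.values())
    trace = pd.DataFrame(
        [{"subtype": s, "n_sensitive_drugs": len(per_subtype[s]),
          "n_specific": len(specific[s])} for s in per_subtype]
    ).set_index("subtype")
    return DrugStratification(sens.reset_index(drop=True), per_subtype, universal,
                              specific, shared, excluded, trace)


def sbs_drug_match(
    exposures: pd.DataFrame,
    sbs_drug_table: pd.DataFrame,
    activity_floor: float = 0.05,
) -> pd.DataFrame:
    """Join per-sample signature fractions with a (signature, drug, direction)
    marker table.

    For every sample and signature whose exposure fraction is at or above the
    activity floor, each marker drug for that signature is listed as
    ``recommended`` (direction 'sensitive') or ``contraindicated``
    ('resistant'), together with the supporting exposure level.
    """
    need = {"signature", "drug", "direction"}
    if not need.issubset(sbs_drug_table.columns):
        raise ValueError("marker table needs signature/drug/direction columns")
    shared = sorted(set(exposures.index) & set(sbs_drug_table["signature"]))
    if not shared:
        warnings.warn("no signature shared between exposures and marker table",
                      stacklevel=2)
        return pd.DataFrame(columns=["sample", "signature", "exposure", "drug",
                                     "direction", "call"])
    rows = []
    markers = sbs_drug_table[sbs_drug_table["signature"].isin(shared)]
    for sample in exposures.columns:
        for sig in shared:
            level = float(exposures.loc[sig, sample])
            if level < activity_floor:
                continue
            for _, m in markers[markers["signature"] == sig].iterrows():
                call = "recommended" if m["direction"] == "sensitive" else "contraindicated"
                rows.append({"sample": sample, "signature": sig, "exposure": level,
                             "drug": m["drug"], "direction": m["direction"],
                             "call": call})
    return pd.DataFrame(rows, columns=["sample", "signature", "exposure", "drug",
                                       "direction", "call"])


def immunophenotype(
    cell_scores: pd.DataFrame,
    seed: int = 0,
    reps: int = 50,
    subsample: float = 0.8,
):
    """Two-class immunophenotype from a cell-type x sample score matrix.

    Rows are z-scored, samples are consensus-clustered at k = 2, and the
    class with the higher mean aggregate z-score is labelled
    ``immune-inflamed``, the other ``immune-desert``.  Returns ``(labels,
    per-class mean-score summary)``.
    """
    if cell_scores.shape[0] < 2 or cell_scores.shape[1] < 10:
        raise ValueError("need >= 2 cell types and >= 10 samples")
    X = cell_scores.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).all():
        raise ValueError("degenerate score matrix: all cell types constant")
    keep = sd[:, 0] > 0
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep]
    zdf = pd.DataFrame(Z, index=cell_scores.index[keep], columns=cell_scores.columns)
    res = consensus_cluster(zdf, k_range=[2], reps=reps, subsample=subsample,
                            seed=seed)
    lab = res.labels[2]
    agg = zdf.mean(axis=0)
    means = agg.groupby(lab).mean()
    inflamed = means.idxmax()
    names = {c: ("immune-inflamed" if c == inflamed else "immune-desert")
             for c in means.index}
    labels = lab.map(names).rename("immunophenotype")
    summary = pd.DataFrame({
        "mean_aggregate_z": means,
        "phenotype": [names[c] for c in means.index],
        "n_samples": lab.value_counts().reindex(means.index),
    })
    return labels, summary
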