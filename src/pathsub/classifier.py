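"""A small feedforward subtype predictor over hub-gene expression.

Architecture: per-gene standardisation (training-set mean/SD, frozen at
training), one hidden layer of six logistic units, softmax output over the k
subtypes, trained by full-batch gradient descent on cross-entropy.  Each
gradient step is accepted only if it does not increase the loss; otherwise
the learning rate is halved and the step retried, so the recorded loss trace
is non-increasing by construction and training is exactly reproducible from
the seed.

External cohorts are harmonised by per-gene z-scoring *within* the external
dataset (a cross-platform assumption, recorded in the model metadata);
missing genes are imputed at the standardised mean (0) and logged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from ._utils import rng_from_seed

__all__ = [
    "SubtypeClassifier",
    "EvalReport",
    "TrainConfig",
    "train_classifier",
    "predict_subtypes",
    "evaluate_classifier",
]


@dataclass
class TrainConfig:
    hidden_units: int = 6
    epochs: int = 2000
    learning_rate: float = 0.01
    seed: int = 0
    max_halvings: int = 40


@dataclass
class EvalReport:
    accuracy: float
    f1_per_class: dict
    macro_f1: float
    weighted_f1: float
    auc_per_class: dict
    confusion: pd.DataFrame
    fold_assignments: pd.Series | None = None
    per_fold: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for v in [self.accuracy, self.macro_f1, self.weighted_f1]:
            if not (0.0 <= v <= 1.0):
                raise ValueError("metrics must lie in [0, 1]")


@dataclass
class SubtypeClassifier:
    genes: list
    classes: list
    mu: np.ndarray                    # per-gene training means
    sd: np.ndarray                    # per-gene training SDs
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: TrainConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    # ------------------------------------------------------------ core ----
    def _forward(self, Z: np.ndarray):
        Hid = 1.0 / (1.0 + np.exp(-(Z @ self.W1 + self.b1)))
        logits = Hid @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return Hid, expl / expl.sum(axis=1, keepdims=True)

    def predict_proba_standardised(self, Z: np.ndarray) -> np.ndarray:
        return self._forward(Z)[1]

    def predict(self, expr: pd.DataFrame):
        """Predict from gene x sample expression using the frozen training
        scalers (no within-dataset harmonisation)."""
        Z = self._standardise(expr)
        proba = self.predict_proba_standardised(Z)
        labels = [self.classes[i] for i in np.argmax(proba, axis=1)]
        return (pd.Series(labels, index=expr.columns, name="subtype"),
                pd.DataFrame(proba, index=expr.columns, columns=self.classes))

    def _standardise(self, expr: pd.DataFrame) -> np.ndarray:
        X = expr.reindex(self.genes).to_numpy(dtype=float).T
        return (X - self.mu) / self.sd

    # ------------------------------------------------------- persistence --
    def to_json(self) -> str:
        payload = {
            "genes": list(self.genes),
            "classes": [str(c) for c in self.classes],
            "mu": self.mu.tolist(),
            "sd": self.sd.tolist(),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "config": {
                "hidden_units": self.config.hidden_units,
                "epochs": self.config.epochs,
                "learning_rate": self.config.learning_rate,
                "seed": self.config.seed,
                "max_halvings": self.config.max_halvings,
            },
            "loss_trace": [float(v) for v in self.loss_trace],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SubtypeClassifier":
        d = json.loads(text)
        return cls(
            genes=d["genes"], classes=d["classes"],
            mu=np.array(d["mu"]), sd=np.array(d["sd"]),
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=np.array(d["b2"]),
            config=TrainConfig(**d["config"]),
            loss_trace=np.array(d["loss_trace"]),
        )


def _cross_entropy(proba: np.ndarray, y_idx: np.ndarray) -> float:
    return float(-np.mean(np.log(np.maximum(proba[np.arange(len(y_idx)), y_idx],
                                            1e-300))))


def _fit(Z: np.ndarray, y_idx: np.ndarray, n_classes: int, config: TrainConfig):
    rng = rng_from_seed(config.seed)
    g, h, k = Z.shape[1], config.hidden_units, n_classes
    W1 = rng.normal(0.0, 1.0 / np.sqrt(g), size=(g, h))
    b1 = np.zeros(h)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, k))
    b2 = np.zeros(k)
    Y = np.zeros((len(y_idx), k))
    Y[np.arange(len(y_idx)), y_idx] = 1.0
    n = len(y_idx)

    def forward(params):
        W1_, b1_, W2_, b2_ = params
        Hid = 1.0 / (1.0 + np.exp(-(Z @ W1_ + b1_)))
        logits = Hid @ W2_ + b2_
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        proba = expl / expl.sum(axis=1, keepdims=True)
        return Hid, proba

    params = (W1, b1, W2, b2)
    Hid, proba = forward(params)
    loss = _cross_entropy(proba, y_idx)
    trace = [loss]
    lr = config.learning_rate
    for _ in range(config.epochs):
        delta_out = (proba - Y) / n
        gW2 = Hid.T @ delta_out
        gb2 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ params[2].T) * Hid * (1.0 - Hid)
        gW1 = Z.T @ delta_hid
        gb1 = delta_hid.sum(axis=0)
        accepted = False
        for _h in range(config.max_halvings):
            cand = (params[0] - lr * gW1, params[1] - lr * gb1,
                    params[2] - lr * gW2, params[3] - lr * gb2)
            Hid_c, proba_c = forward(cand)
            loss_c = _cross_entropy(proba_c, y_idx)
            if loss_c <= loss:
                params, Hid, proba, loss = cand, Hid_c, proba_c, loss_c
                accepted = True
                break
            lr *= 0.5
        trace.append(loss)
        if not accepted:
            break
    return params, np.array(trace)


def _stratified_split(labels: np.ndarray, train_frac: float, rng):
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples for a stratified split")
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(train_idx), np.sort(test_idx)


def _report(y_true, y_pred, proba, classes, folds=None, per_fold=None) -> EvalReport:
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    f1s = f1_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    aucs = {}
    y_true = np.asarray(y_true)
    for ci, c in enumerate(classes):
        ind = (y_true == c).astype(int)
        aucs[c] = (float(roc_auc_score(ind, proba[:, ci]))
                   if 0 < ind.sum() < len(ind) else float("nan"))
    return EvalReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1_per_class={c: float(v) for c, v in zip(classes, f1s)},
        macro_f1=float(f1_score(y_true, y_pred, labels=classes, average="macro",
                                zero_division=0)),
        weighted_f1=float(f1_score(y_true, y_pred, labels=classes,
                                   average="weighted", zero_division=0)),
        auc_per_class=aucs,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        fold_assignments=folds,
        per_fold=per_fold,
    )


def train_classifier(
    hub_expr: pd.DataFrame,
    labels: pd.Series,
    split: float = 0.8,
    config: TrainConfig | None = None,
    seed: int = 0,
):
    """Train on a stratified ``split`` fraction and evaluate on the rest.

    Scalers are fitted on the training split only and frozen into the model.
    Returns ``(model, holdout_report)``.
    """
    config = config or TrainConfig(seed=seed)
    labels = labels.reindex(hub_expr.columns)
    y = labels.to_numpy()
    classes = sorted(pd.unique(y))
    rng = rng_from_seed(seed)
    tr, te = _stratified_split(y, split, rng)
    if len(np.unique(y[tr])) < len(classes):
        raise ValueError("a class is absent from the training split")

    X = hub_expr.to_numpy(dtype=float).T
    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    y_idx = np.searchsorted(np.array(classes), y)
    (W1, b1, W2, b2), trace = _fit(Z[tr], y_idx[tr], len(classes), config)
    model = SubtypeClassifier(list(hub_expr.index), classes, mu, sd,
                              W1, b1, W2, b2, config, trace)
    proba = model.predict_proba_standardised(Z[te])
    y_pred = [classes[i] for i in np.argmax(proba, axis=1)]
    return model, _report(y[te], y_pred, proba, classes)


def predict_subtypes(model: SubtypeClassifier, expr_external: pd.DataFrame,
                     harmonize: bool = True):
    """Apply the classifier to an external cohort.

    With ``harmonize`` (default) genes are z-scored within the external
    dataset; at least 80% of the model's genes must be present; the rest are
    imputed at 0 after z-scoring (logged via a warning).  Returns
    ``(labels, probabilities)``.
    """
    present = [g for g in model.genes if g in expr_external.index]
    missing = [g for g in model.genes if g not in expr_external.index]
    if len(present) < 0.8 * len(model.genes):
        raise ValueError(f"only {len(present)}/{len(model.genes)} model genes "
                         f"present; missing: {', '.join(missing)}")
    if missing:
        warnings.warn(f"{len(missing)} model gene(s) absent, imputed at 0: "
                      f"{', '.join(missing)}", stacklevel=2)
    n = expr_external.shape[1]
    Z = np.zeros((n, len(model.genes)))
    if harmonize:
        sub = expr_external.loc[present].to_numpy(dtype=float)
        sd = sub.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        zz = (sub - sub.mean(axis=1, keepdims=True)) / sd
        for zi, g in enumerate(present):
            Z[:, model.genes.index(g)] = zz[zi]
    else:
        Z = model._standardise(expr_external)
        for g in missing:
            Z[:, model.genes.index(g)] = 0.0
    proba = model.predict_proba_standardised(Z)
    labels = [model.classes[i] for i in np.argmax(proba, axis=1)]
    return (pd.Series(labels, index=expr_external.columns, name="subtype"),
            pd.DataFrame(proba, index=expr_external.columns, columns=model.classes))


def evaluate_classifier(
    hub_expr: pd.DataFrame,
    labels: pd.Series,
    folds: int = 5,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation: a fresh model per fold, pooled
    predictions scored with per-fold metrics alongside.  Folds are reduced
    (with a warning) when the smallest class has fewer members than folds."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    config = config or TrainConfig(seed=seed)
    labels = labels.reindex(hub_expr.columns)
    y = labels.to_numpy()
    classes = sorted(pd.unique(y))
    min_class = min(np.bincount(np.searchsorted(np.array(classes), y)))
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} samples; reducing folds",
                      stacklevel=2)
        folds = max(2, min_class)
    X = hub_expr.to_numpy(dtype=float).T
    y_idx = np.searchsorted(np.array(classes), y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    pooled_pred = np.empty(len(y), dtype=object)
    pooled_proba = np.zeros((len(y), len(classes)))
    fold_of = np.zeros(len(y), dtype=int)
    fold_rows = []
    for f, (tr, te) in enumerate(skf.split(X, y_idx)):
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (X - mu) / sd
        params, _ = _fit(Z[tr], y_idx[tr], len(classes), config)
        model = SubtypeClassifier(list(hub_expr.index), classes, mu, sd,
                                  *params, config)
        proba = model.predict_proba_standardised(Z[te])
        pred = [classes[i] for i in np.argmax(proba, axis=1)]
        pooled_pred[te] = pred
        pooled_proba[te] = proba
        fold_of[te] = f
        fold_rows.append({"fold": f,
                          "accuracy": float(accuracy_score(y[te], pred)),
                          "macro_f1": float(f1_score(y[te], pred, labels=classes,
                                                     average="macro",
                                                     zero_division=0))})
    return _report(
        y, list(pooled_pred), pooled_proba, classes,
        folds=pd.Series(fold_of, index=hub_expr.columns, name="fold"),
        per_fold=pd.DataFrame(fold_rows).set_index("fold"),
    )
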