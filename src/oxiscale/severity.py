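"""Apnea-severity labelling and the repeated train/test evaluation protocol.

Severity is derived from the AHI with the clinical cut-offs 5, 15 and
30 events/h: three binary tasks (positive = at/above the cut-off) and one
four-class task (normal / mild / moderate / severe).  Evaluation follows a
stratified 80/20 split, training-set standard scaling and median imputation,
per-model grid search with 5-fold cross-validation, and repetition over many
random seeds with mean/SD reporting.

Models are consumed behind a fit/predict(_proba) interface; the registry
covers naive Bayes, logistic regression, decision tree, k-NN, two
gradient-boosted tree ensembles (XGBoost, LightGBM) and a basic MLP.
Metrics (accuracy, precision, sensitivity, F1, MCC, AUC) are computed from
stored confusion counts in closed form, with the Gorodkin generalisation of
MCC for the multiclass task.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

CUTOFFS = (5.0, 15.0, 30.0)
SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")
TASKS = ("cutoff5", "cutoff15", "cutoff30", "multiclass")


class ConfigError(ValueError):
    pass


def label_severity(labels: pd.DataFrame) -> pd.DataFrame:
    """Binary and multiclass severity labels from per-subject AHI.

    Input needs columns ``subject_id`` and ``ahi``; output adds ``cutoff5``,
    ``cutoff15``, ``cutoff30`` (1 = at/above the cut-off) and ``multiclass``
    (0=normal, 1=mild, 2=moderate, 3=severe).
    """
    if (labels["ahi"] < 0).any():
        raise ValueError("AHI must be non-negative")
    out = labels[["subject_id", "ahi"]].copy()
    ahi = out["ahi"].to_numpy(dtype=float)
    for c in CUTOFFS:
        out[f"cutoff{c:g}"] = (ahi >= c).astype(int)
    out["multiclass"] = np.digitize(ahi, CUTOFFS)  # right-open bins, >= cutoff
    return out


@dataclass(frozen=True)
class EvalMetrics:
    """One experiment's held-out metrics plus the confusion counts behind them."""

    acc: float
    pre: float
    sen: float
    f1: float
    mcc: float
    auc: float | None
    confusion: np.ndarray

    def as_dict(self) -> Dict[str, float]:
        d = {"acc": self.acc, "pre": self.pre, "sen": self.sen,
             "f1": self.f1, "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def compute_metrics(
    confusion: np.ndarray, scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> EvalMetrics:
    """Closed-form metrics from a confusion matrix (rows = truth, cols = prediction).

    Binary (2x2, positive class = index 1): precision/sensitivity/F1 for the
    positive class and the standard MCC; AUC from ``scores`` (positive-class
    scores, with ``y_true``) when supplied.  Larger matrices: macro-averaged
    precision/sensitivity/F1 and the Gorodkin multiclass MCC; AUC is omitted.
    Undefined ratios (empty denominators) are reported as 0, matching the
    constant-predictor convention MCC = 0.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = c.sum()
    acc = float(np.trace(c) / total) if total else 0.0

    tp = np.diag(c)
    pred_tot = c.sum(axis=0)
    true_tot = c.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec_k = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec_k = np.where(true_tot > 0, tp / true_tot, 0.0)
        f1_k = np.where(prec_k + rec_k > 0, 2 * prec_k * rec_k / (prec_k + rec_k), 0.0)

    if c.shape[0] == 2:
        pre, sen, f1 = float(prec_k[1]), float(rec_k[1]), float(f1_k[1])
        tn, fp, fn, tp2 = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
        denom = math.sqrt((tp2 + fp) * (tp2 + fn) * (tn + fp) * (tn + fn))
        mcc = float((tp2 * tn - fp * fn) / denom) if denom else 0.0
        auc = None
        if scores is not None and y_true is not None and np.unique(y_true).size == 2:
            auc = _binary_auc(np.asarray(y_true), np.asarray(scores, dtype=float))
    else:
        pre, sen, f1 = float(prec_k.mean()), float(rec_k.mean()), float(f1_k.mean())
        mcc = _gorodkin_mcc(c)
        auc = None
    return EvalMetrics(acc=acc, pre=pre, sen=sen, f1=f1, mcc=mcc, auc=auc, confusion=c)


def _gorodkin_mcc(c: np.ndarray) -> float:
    """Rk statistic: multiclass MCC from the confusion matrix."""
    s = c.sum()
    cov = np.trace(c) * s - (c.sum(axis=0) * c.sum(axis=1)).sum()
    d1 = s * s - (c.sum(axis=0) ** 2).sum()
    d2 = s * s - (c.sum(axis=1) ** 2).sum()
    denom = math.sqrt(d1 * d2)
    return float(cov / denom) if denom else 0.0


def _binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC (Mann-Whitney with tie correction)."""
    from scipy.stats import rankdata

    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _model_and_grid(model_id: str, seed: int) -> tuple[BaseEstimator, dict]:
    """Registry of classifiers and their (small, documented) search grids."""
    if model_id == "NB":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB(), {"model__var_smoothing": [1e-9, 1e-7]}
    if model_id == "LR":
        from sklearn.linear_model import LogisticRegression

        return (LogisticRegression(max_iter=2000, random_state=seed),
                {"model__C": [0.1, 1.0, 10.0]})
    if model_id == "DT":
        from sklearn.tree import DecisionTreeClassifier

        return (DecisionTreeClassifier(random_state=seed),
                {"model__max_depth": [3, 6, None]})
    if model_id == "KNN":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(), {"model__n_neighbors": [5, 11]}
    if model_id == "XGB":
        from xgboost import XGBClassifier

        return (XGBClassifier(n_estimators=100, random_state=seed,
                              verbosity=0, n_jobs=1),
                {"model__max_depth": [3, 5]})
    if model_id == "LGBM":
        from lightgbm import LGBMClassifier

        return (LGBMClassifier(n_estimators=100, random_state=seed,
                               verbosity=-1, n_jobs=1),
                {"model__num_leaves": [15, 31]})
    if model_id == "MLP":
        from sklearn.neural_network import MLPClassifier

        return (MLPClassifier(hidden_layer_sizes=(32,), max_iter=500,
                              random_state=seed),
                {"model__alpha": [1e-4, 1e-2]})
    raise ConfigError(f"unknown model id {model_id!r}; "
                      "choose from NB, LR, DT, KNN, XGB, LGBM, MLP")


def _task_labels(y: pd.DataFrame, task: str) -> np.ndarray:
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}; choose from {TASKS}")
    return y[task if task != "multiclass" else "multiclass"].to_numpy()


def run_experiment(
    m: pd.DataFrame,
    y: pd.DataFrame,
    task: str,
    model_id: str,
    seed: int,
    cv_folds: int = 5,
    test_size: float = 0.2,
) -> EvalMetrics:
    """One seeded train/test evaluation.

    Stratified 80/20 split; median imputation and standard scaling are fitted
    on the training rows only; hyperparameters are grid-searched with
    ``cv_folds``-fold CV on the training rows; metrics come from the held-out
    20 %.  Identical seeds give identical metrics.
    """
    y = y.set_index("subject_id").loc[m.index].reset_index()
    target = _task_labels(y, task)
    classes = np.unique(target)
    if classes.size < 2:
        raise ValueError("task has a single class; nothing to learn")
    x = m.to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, target, test_size=test_size, random_state=seed, stratify=target
    )
    model, grid = _model_and_grid(model_id, seed)
    pipe = Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("model", model),
    ])
    search = GridSearchCV(pipe, grid, cv=cv_folds, n_jobs=1)
    search.fit(x_tr, y_tr)
    y_pred = search.predict(x_te)

    n_classes = classes.size
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_te, y_pred):
        confusion[idx[t], idx[p]] += 1
    scores = None
    if n_classes == 2 and hasattr(search, "predict_proba"):
        scores = search.predict_proba(x_te)[:, 1]
    return compute_metrics(confusion, scores=scores, y_true=y_te)


def repeat_experiments(
    m: pd.DataFrame,
    y: pd.DataFrame,
    tasks: Sequence[str],
    models: Sequence[str],
    n_repeats: int = 50,
    base_seed: int = 0,
    cv_folds: int = 5,
) -> pd.DataFrame:
    """Mean/SD of every metric over seeds base_seed..base_seed+n_repeats-1.

    Returns a tidy frame ``model, task, metric, mean, sd, n_effective``; a
    ``confusion_pct`` mean confusion matrix (percent of test subjects) is
    attached per (model, task) in the frame's ``attrs``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rows = []
    confusions: dict[tuple[str, str], np.ndarray] = {}
    for model_id in models:
        for task in tasks:
            per_metric: dict[str, list[float]] = {}
            conf_acc = None
            n_ok = 0
            for k in range(n_repeats):
                seed = base_seed + k
                try:
                    res = run_experiment(m, y, task, model_id, seed, cv_folds=cv_folds)
                except Exception as exc:
                    logger.warning("run %s/%s seed %d failed: %s",
                                   model_id, task, seed, exc)
                    continue
                n_ok += 1
                for name, value in res.as_dict().items():
                    per_metric.setdefault(name, []).append(value)
                pct = 100.0 * res.confusion / res.confusion.sum()
                conf_acc = pct if conf_acc is None else conf_acc + pct
            if n_ok == 0:
                logger.warning("all repeats failed for %s/%s", model_id, task)
                continue
            for name, values in per_metric.items():
                arr = np.asarray(values, dtype=float)
                rows.append({
                    "model": model_id, "task": task, "metric": name,
                    "mean": float(np.nanmean(arr)),
                    "sd": float(np.nanstd(arr)),
                    "n_effective": n_ok,
                })
            confusions[(model_id, task)] = conf_acc / n_ok
    report = pd.DataFrame(rows)
    report.attrs["confusion_pct"] = confusions
    return report
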