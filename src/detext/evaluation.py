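"""Metrics and experiment harnesses.

Provides the binary-classification report (accuracy, recall, precision, F1,
ROC/AUC), a train-fraction sweep that traces how performance grows with the
training share, a signature-coefficient sweep, and a regularization sweep
over dropout rate and the max-norm constraint with exported loss and
learning curves.  Splits are stratified independent draws: each fraction is
a fresh seeded split preserving class proportions, not a rotated fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .model import ModelConfig, TrainingHistory, as_arrays, predict, train

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "roc_auc",
    "stratified_split",
    "train_fraction_sweep",
    "coefficient_sweep",
    "regularization_sweep",
    "average_roc",
]


@dataclass
class MetricsReport:
    """Confusion counts and derived rates; undefined ratios are None."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None
    curve: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Exact confusion counts and the standard derived rates.

    ``predictions`` are hard 0/1 calls; pass continuous ``scores`` as well to
    get the ROC curve and AUC.  Ratios whose denominator is zero (e.g.
    precision with no positive prediction) are reported as None, not 0.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and (precision + recall) > 0
        else None
    )
    auc = curve = None
    if scores is not None and len(np.unique(y)) == 2:
        auc, curve = roc_auc(y, scores)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(y),
        recall=recall, precision=precision, f1=f1,
        auc=auc, curve=curve,
    )


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Empirical ROC curve and trapezoidal AUC (ties grouped by threshold)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return float(_skm.auc(fpr, tpr)), (fpr, tpr)


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split preserving class proportions.

    Each class contributes ``round(fraction * class size)`` examples to the
    training side, so class proportions differ by at most one example.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train fraction must be in (0, 1), got {train_fraction}")
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _subset(arrays, idx):
    tokens, priors, labels = arrays
    return _ArrayDataset(tokens[idx], priors[idx], labels[idx])


@dataclass
class _ArrayDataset:
    tokens: np.ndarray
    priors: np.ndarray
    labels: np.ndarray


def _evaluate(params, config, test) -> MetricsReport:
    scores = predict(params, test, config)
    return compute_metrics(
        test.labels, (scores >= config.threshold).astype(int), scores
    )


def average_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertically average ROC curves on a common FPR grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    return grid, np.mean(tprs, axis=0)


def train_fraction_sweep(
    dataset,
    config: ModelConfig,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Train a fresh model per train fraction and report test metrics.

    Returns a tidy table (fraction, n_train, n_test, accuracy, auc, ...) and
    a dict of per-fraction ROC curves plus their vertical average.
    """
    arrays = as_arrays(dataset)
    rng = np.random.default_rng(seed)
    rows, curves = [], {}
    for frac in fractions:
        tr_idx, te_idx = stratified_split(arrays[2], frac, rng)
        cfg = replace(config, seed=int(rng.integers(2**31)))
        params, _ = train(_subset(arrays, tr_idx), cfg)
        report = _evaluate(params, cfg, _subset(arrays, te_idx))
        rows.append(
            {
                "fraction": frac,
                "n_train": len(tr_idx),
                "n_test": len(te_idx),
                "accuracy": report.accuracy,
                "recall": report.recall,
                "precision": report.precision,
                "f1": report.f1,
                "auc": report.auc,
            }
        )
        curves[frac] = report.curve
    mean_curve = average_roc([c for c in curves.values() if c is not None])
    return pd.DataFrame(rows), {"per_fraction": curves, "average": mean_curve}


def coefficient_sweep(
    train_set,
    test_set,
    config: ModelConfig,
    coefficients: Sequence[float] = tuple(range(11)),
) -> pd.DataFrame:
    """Train/evaluate once per signature coefficient (0 = no-prior ablation).

    Emits one row per coefficient with the iteration count at convergence,
    AUC and accuracy on the held-out test set.
    """
    rows = []
    for coef in coefficients:
        cfg = replace(config, ms_coefficient=float(coef))
        params, history = train(train_set, cfg)
        report = _evaluate(params, cfg, test_set)
        rows.append(
            {
                "coefficient": coef,
                "iters": history.converged_at,
                "auc": report.auc,
                "acc": report.accuracy,
            }
        )
    return pd.DataFrame(rows)


def regularization_sweep(
    train_set,
    test_set,
    config: ModelConfig,
    dropout_grid: Sequence[float] = tuple(i / 10 for i in range(10)),
    norm_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
) -> tuple[pd.DataFrame, dict[str, TrainingHistory]]:
    """Sensitivity of the regularizers, plus loss/learning curves per cell.

    Dropout varies with the max-norm fixed at the config value; the norm
    constraint varies with dropout fixed; a "None" cell disables both
    (dropout 0, norm constraint effectively unbounded).
    """
    cells: list[tuple[str, ModelConfig]] = []
    for p in dropout_grid:
        cells.append((f"dropout={p:g}", replace(config, dropout_rate=p)))
    for s in norm_grid:
        cells.append((f"norm={s:g}", replace(config, norm_constraint=s)))
    cells.append(
        ("None", replace(config, dropout_rate=0.0, norm_constraint=1e9))
    )
    rows, histories = [], {}
    for name, cfg in cells:
        params, history = train(train_set, cfg)
        report = _evaluate(params, cfg, test_set)
        histories[name] = history
        rows.append(
            {
                "cell": name,
                "dropout": cfg.dropout_rate,
                "norm_constraint": cfg.norm_constraint,
                "iters": history.converged_at,
                "acc": report.accuracy,
                "auc": report.auc,
            }
        )
    return pd.DataFrame(rows), histories
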