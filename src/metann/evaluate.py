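"""Cross-validated benchmarking, classification metrics and diagnostics.

F1-micro follows the pooled definition (equal to multiclass accuracy),
F1-macro is the unweighted mean of per-class F1 scores, AUC is the
micro-averaged one-vs-rest ROC area, and the performance gain is the relative
improvement of the best neural model's F1 over the best classical model's,
reported as an integer percentage.

The harness runs shared stratified k-fold splits: per fold and per run the
preprocessing scaler is fitted on the training fold only, optional NB
augmentation enlarges the training fold only, every model trains on the same
data and is scored on the untouched held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from . import baselines as _baselines
from . import nn_models as _nn
from .baselines import BaselineSpec
from .io_config import OTUTable, RunConfig
from .nb_model import augment_training_set
from .nn_models import CNNSpec, MLPSpec, phylo_sort
from .preprocess import (
    apply_rescaler,
    filter_low_prevalence,
    fit_rescaler,
    to_relative_abundance,
)

__all__ = [
    "ConfusionSummary",
    "MetricsReport",
    "f1_micro",
    "f1_macro",
    "roc_auc",
    "performance_gain",
    "cross_validate",
    "qq_points",
    "adjusted_r_squared",
]

METRICS = ("f1_macro", "f1_micro", "auc")


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionSummary:
    """Per-class true positives, false positives and false negatives."""

    classes: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionSummary":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.size == 0:
            raise EvaluationError("empty prediction set")
        if y_true.shape != y_pred.shape:
            raise EvaluationError("y_true and y_pred differ in length")
        classes = np.unique(np.concatenate([y_true, y_pred]))
        tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes])
        fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes])
        fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes])
        return cls(classes, tp, fp, fn, int(y_true.size))


def f1_micro(confusion: ConfusionSummary) -> float:
    """Pooled F1 — true positives over total samples, i.e. accuracy."""
    if confusion.n <= 0:
        raise EvaluationError("empty confusion summary")
    return float(confusion.tp.sum() / confusion.n)


def f1_macro(confusion: ConfusionSummary) -> float:
    """Unweighted mean over classes of 2TP/(2TP+FP+FN).

    A class with no true and no predicted instances contributes an F1 of 0
    (with a warning), matching the imbalance-blind definition.
    """
    if confusion.n <= 0:
        raise EvaluationError("empty confusion summary")
    denom = 2 * confusion.tp + confusion.fp + confusion.fn
    if np.any(denom == 0):
        warnings.warn("class with zero support scored as F1=0", stacklevel=2)
    per_class = np.where(denom > 0, 2 * confusion.tp / np.maximum(denom, 1), 0.0)
    return float(per_class.mean())


def roc_auc(scores: np.ndarray, labels) -> float:
    """Micro-averaged one-vs-rest ROC area (trapezoidal).

    ``scores`` is an (n x K) score matrix whose columns follow the sorted
    unique labels; all class indicator/score pairs are pooled into one binary
    ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise EvaluationError("AUC undefined for a single class")
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    if scores.shape != (labels.size, classes.size):
        raise EvaluationError("scores must be n x K for the observed classes")
    onehot = (labels[:, None] == classes[None, :]).astype(int)
    fpr, tpr, _ = roc_curve(onehot.ravel(), scores.ravel())
    return float(auc(fpr, tpr))


def performance_gain(best_nn_f1: float, best_ml_f1: float) -> float:
    """Relative gain 100*(best_nn - best_ml)/best_ml in percent.

    Reported values are rounded to the nearest integer percent; the raw
    percentage is returned here.
    """
    if best_ml_f1 <= 0:
        raise EvaluationError("gain undefined for a non-positive baseline score")
    return 100.0 * (best_nn_f1 - best_ml_f1) / best_ml_f1


@dataclass
class MetricsReport:
    """Mean/SD of each metric per model over fold x run cells, plus gains."""

    summary: pd.DataFrame
    fold_scores: pd.DataFrame
    gain_percent: dict = field(default_factory=dict)

    def mean(self, model: str, metric: str) -> float:
        return float(self.summary.loc[model, f"{metric}_mean"])

    def sd(self, model: str, metric: str) -> float:
        return float(self.summary.loc[model, f"{metric}_sd"])


_NN_SPECS = (MLPSpec, CNNSpec)


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    counts = pd.Series(labels).value_counts()
    if counts.min() < n_folds:
        warnings.warn(
            f"smallest class has {counts.min()} members (< {n_folds} folds); "
            "falling back to unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(splitter.split(labels))
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(labels, dtype=float), labels))


def _train_one(name, spec, features, labels, ordering, rng):
    if isinstance(spec, MLPSpec):
        return _nn.train_mlp(features, labels, spec, rng)
    if isinstance(spec, CNNSpec):
        return _nn.train_cnn(features, labels, ordering, spec, rng)
    if isinstance(spec, BaselineSpec):
        return _baselines.train_ovr(spec, features, labels, rng)
    raise EvaluationError(f"model {name!r}: unsupported spec {type(spec).__name__}")


def _score_one(model, features):
    if isinstance(model, _nn.TrainedModel):
        scores = _nn.predict_proba(model, features)
    else:
        scores = _baselines.decision_scores(model, features)
    preds = model.classes[np.argmax(scores, axis=1)]
    return scores, preds, model.classes


def cross_validate(
    table: OTUTable,
    models: Mapping[str, object],
    config: RunConfig,
) -> MetricsReport:
    """Benchmark every model with shared stratified folds.

    Pipeline per (run, fold): split counts; optionally augment the training
    fold with NB samples; convert both folds to relative abundance; fit the
    min-max rescaler on the training fold (augmented rows included, they are
    training data) and apply it to both; train; score the held-out fold.
    The prevalence filter runs once up front — it is label-blind, so this
    cannot leak fold information.
    """
    if not models:
        raise EvaluationError("no models to evaluate")
    table = filter_low_prevalence(table, config.min_prevalence)
    labels = table.label_vector()
    ordering = phylo_sort(table.otu_ids, table.taxonomy)

    root = np.random.SeedSequence(config.seed)
    fold_seed = int(np.random.default_rng(root.spawn(1)[0]).integers(2**31))
    folds = _stratified_folds(labels, config.n_folds, fold_seed)

    rows = []
    for run in range(config.n_runs):
        run_ss = np.random.SeedSequence(config.seed).spawn(run + 2)[-1]
        for k, (train_idx, val_idx) in enumerate(folds):
            child = run_ss.spawn(k + 1)[-1]
            aug_rng, model_seed_rng = (np.random.default_rng(s) for s in child.spawn(2))
            train_tab = table.select_samples(train_idx)
            val_tab = table.select_samples(val_idx)
            if config.augment:
                train_tab = augment_training_set(train_tab, "match", aug_rng)
            train_ab = to_relative_abundance(train_tab)
            val_ab = to_relative_abundance(val_tab)
            if config.rescale:
                state = fit_rescaler(train_ab)
                train_ab = apply_rescaler(train_ab, state)
                val_ab = apply_rescaler(val_ab, state)
            y_train = train_tab.label_vector()
            y_val = val_tab.label_vector()
            for name, spec in models.items():
                rng = np.random.default_rng(model_seed_rng.integers(2**31))
                model = _train_one(name, spec, train_ab, y_train, ordering, rng)
                scores, preds, model_classes = _score_one(model, val_ab)
                conf = ConfusionSummary.from_predictions(y_val, preds)
                try:
                    fold_auc = roc_auc(
                        scores[:, np.isin(model_classes, np.unique(y_val))]
                        if scores.shape[1] != np.unique(y_val).size
                        else scores,
                        y_val,
                    )
                except EvaluationError:
                    fold_auc = np.nan
                rows.append(
                    {
                        "model": name,
                        "run": run,
                        "fold": k,
                        "f1_micro": f1_micro(conf),
                        "f1_macro": f1_macro(conf),
                        "auc": fold_auc,
                    }
                )

    fold_scores = pd.DataFrame(rows)
    summary = pd.DataFrame(index=list(models))
    for metric in METRICS:
        grouped = fold_scores.groupby("model")[metric]
        summary[f"{metric}_mean"] = grouped.mean()
        summary[f"{metric}_sd"] = grouped.std(ddof=0)

    gain = {}
    nn_names = [n for n, s in models.items() if isinstance(s, _NN_SPECS)]
    ml_names = [n for n, s in models.items() if isinstance(s, BaselineSpec)]
    if nn_names and ml_names:
        for metric in ("f1_macro", "f1_micro"):
            best_nn = max(summary.loc[n, f"{metric}_mean"] for n in nn_names)
            best_ml = max(summary.loc[n, f"{metric}_mean"] for n in ml_names)
            if best_ml > 0:
                gain[metric] = int(round(performance_gain(best_nn, best_ml)))
    return MetricsReport(summary, fold_scores, gain)


def qq_points(sample_a, sample_b) -> np.ndarray:
    """Quantile-quantile pairs of two count vectors.

    Both vectors are sorted; sample_b is evaluated by linear interpolation on
    sample_a's quantile grid, giving len(sample_a) pairs. Identical inputs
    fall on the diagonal.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("Q-Q plot needs non-empty samples")
    grid = np.linspace(0.0, 1.0, a.size) if a.size > 1 else np.array([0.5])
    qb = np.quantile(b, grid)  # linear interpolation between order statistics
    return np.column_stack([a, qb])


def adjusted_r_squared(x, y) -> float:
    """Adjusted R^2 of the simple OLS fit y ~ x: 1 - (1-R^2)(n-1)/(n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise EvaluationError("adjusted R^2 needs at least 3 points")
    if np.ptp(x) == 0:
        raise EvaluationError("slope undefined for constant x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
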