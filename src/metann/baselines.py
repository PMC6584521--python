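"""One-vs-rest classical baselines: SVM, L1/L2 logistic regression, gradient
boosting, random forest and multinomial naive Bayes.

The binary estimators themselves are scikit-learn's; what is bespoke here is
the multiclass protocol: one binary classifier per class against the rest,
hyperparameters for the tuned kinds (SVM, RF) selected by an inner 3-fold
cross-validation on the training data only, and prediction by the "strongest
vote" — the class whose binary model produces the largest decision score
(probability where the estimator is natively probabilistic, margin otherwise),
ties broken toward the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC

from .preprocess import AbundanceMatrix

__all__ = ["BaselineSpec", "OVRModel", "train_ovr", "decision_scores", "predict"]

KINDS = ("svm", "lr_l1", "lr_l2", "gb", "rf", "mnb")

# one grid point per decade, per the published tuning ranges
_C_GRID = [1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
_GAMMA_GRID = [1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 1e1]


class BaselineError(ValueError):
    pass


@dataclass
class BaselineSpec:
    """One baseline family plus its tuning grid.

    ``grid=None`` selects the default protocol for the kind: SVM tunes kernel
    (linear vs RBF), C over [1e-2..1e3] and RBF width over [1e-5..1e1]; RF
    fixes 200 trees and tunes depth/split granularity; the remaining kinds run
    untuned at their published defaults (GB with max_depth=10 and
    min_samples_split=5; MNB with additive smoothing 1 and empirical class
    priors). ``params`` overrides constructor arguments of the base estimator.
    """

    kind: str
    grid: Sequence[Mapping] | Mapping | None = None
    params: Mapping = field(default_factory=dict)
    inner_cv_folds: int = 3

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise BaselineError(f"unknown baseline kind {self.kind!r}")
        if self.inner_cv_folds < 2:
            raise BaselineError("inner_cv_folds must be at least 2")


@dataclass
class OVRModel:
    kind: str
    classes: np.ndarray
    models: list
    probabilistic: bool


def _base_estimator(kind: str, params: Mapping, seed: int):
    if kind == "svm":
        return SVC(random_state=seed, **params)
    if kind == "lr_l1":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=1000,
            random_state=seed, **params
        )
    if kind == "lr_l2":
        return LogisticRegression(
            l1_ratio=0.0, solver="lbfgs", max_iter=1000, **params
        )
    if kind == "gb":
        kw = {"max_depth": 10, "min_samples_split": 5}
        kw.update(params)
        return GradientBoostingClassifier(random_state=seed, **kw)
    if kind == "rf":
        kw = {"n_estimators": 200}
        kw.update(params)
        return RandomForestClassifier(random_state=seed, **kw)
    if kind == "mnb":
        kw = {"alpha": 1.0, "fit_prior": True}
        kw.update(params)
        return MultinomialNB(**kw)
    raise BaselineError(f"unknown baseline kind {kind!r}")


def _default_grid(kind: str):
    if kind == "svm":
        return [
            {"kernel": ["linear"], "C": _C_GRID},
            {"kernel": ["rbf"], "C": _C_GRID, "gamma": _GAMMA_GRID},
        ]
    if kind == "rf":
        return {"max_depth": [None, 10], "min_samples_split": [2, 5]}
    return None  # untuned kinds


def _as_array(features) -> np.ndarray:
    if isinstance(features, AbundanceMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def train_ovr(
    spec: BaselineSpec,
    features,
    labels,
    rng: np.random.Generator | None = None,
) -> OVRModel:
    """Fit one binary classifier per class against the rest.

    For tuned kinds each binary problem runs its own inner
    ``spec.inner_cv_folds``-fold grid search on the training data only; the
    held-out fold of any outer cross-validation never enters.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = _as_array(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise BaselineError("training requires at least two classes")
    grid = spec.grid if spec.grid is not None else _default_grid(spec.kind)
    models = []
    for c in classes:
        binary = (y == c).astype(int)
        seed = int(rng.integers(2**31))
        est = _base_estimator(spec.kind, spec.params, seed)
        if grid:
            search = GridSearchCV(est, grid, cv=spec.inner_cv_folds, n_jobs=1)
            search.fit(x, binary)
            models.append(search.best_estimator_)
        else:
            models.append(clone(est).fit(x, binary))
    probabilistic = spec.kind != "svm"
    return OVRModel(spec.kind, classes, models, probabilistic)


def decision_scores(model: OVRModel, features) -> np.ndarray:
    """Per-class vote strengths (n x K).

    Probabilistic estimators vote with P(class | x); margin-based ones (SVM)
    with their signed decision function. Row-wise argmax is the prediction;
    numpy's argmax resolves exact ties toward the lowest class index.
    """
    x = _as_array(features)
    n_features = getattr(model.models[0], "n_features_in_", x.shape[1])
    if x.shape[1] != n_features:
        raise BaselineError(
            f"model expects {n_features} features, got {x.shape[1]}"
        )
    cols = []
    for est in model.models:
        if model.probabilistic:
            proba = est.predict_proba(x)
            # column for class "1" (the one-vs-rest positive)
            pos = list(est.classes_).index(1) if 1 in est.classes_ else 0
            cols.append(proba[:, pos])
        else:
            cols.append(est.decision_function(x))
    return np.column_stack(cols)


def predict(model: OVRModel, features) -> np.ndarray:
    """Strongest-vote prediction across the binary classifiers."""
    scores = decision_scores(model, features)
    return model.classes[np.argmax(scores, axis=1)]
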