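"""Per-class negative-binomial moment fitting and training-set augmentation.

One NB distribution is fitted per (class, OTU) pair by the method of moments,
equating the sample mean and variance to the Gamma moments mu = r*theta and
sigma^2 = r*theta^2, which gives

    theta_hat = sigma^2 / mu,        r_hat = mu^2 / sigma^2.

This "paper" convention identifies the Gamma mixing distribution's moments
with the count moments. The NB *marginal* variance is actually
r*theta*(1+theta); the ``nb_marginal`` convention solves that system instead
(theta = sigma^2/mu - 1, r = mu/theta) and is switchable per fit.

A Gamma-Poisson mixture can never be under-dispersed, so OTUs whose sample
variance does not exceed their mean fall back to a plain Poisson at the
sample mean; all-zero OTUs emit zeros. Augmented samples are raw counts and
flow through the same preprocessing path as real counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_config import OTUTable

__all__ = ["ClassNBFit", "NBParams", "fit_nb_moments", "sample_augmented",
           "augment_training_set"]


class NBModelError(ValueError):
    pass


# slack on sigma^2 <= mu*(1+eps) below which the Poisson fallback engages
_UNDERDISPERSION_EPS = 1e-6


@dataclass
class ClassNBFit:
    """Moment-fitted NB parameters for every OTU of one class.

    ``degenerate`` flags OTUs in a fallback regime: where ``mean`` is zero the
    OTU emits zeros, otherwise (under-dispersed) it emits Poisson(mean) draws.
    ``r``/``theta`` are only meaningful where ``degenerate`` is False.
    """

    r: np.ndarray
    theta: np.ndarray
    mean: np.ndarray
    degenerate: np.ndarray
    convention: str = "paper"

    @property
    def n_otus(self) -> int:
        return self.r.size


@dataclass
class NBParams:
    """Per-class NB fits keyed by class label."""

    per_class: dict = field(default_factory=dict)
    convention: str = "paper"

    def to_dict(self, otu_ids=None) -> dict:
        """JSON-ready mapping class -> {otu_id: {r, theta, degenerate}}."""
        out = {}
        for label, fit in self.per_class.items():
            ids = otu_ids if otu_ids is not None else range(fit.n_otus)
            out[label] = {
                str(o): {
                    "r": float(fit.r[j]),
                    "theta": float(fit.theta[j]),
                    "degenerate": bool(fit.degenerate[j]),
                }
                for j, o in enumerate(ids)
            }
        return out


def fit_nb_moments(class_counts: np.ndarray, convention: str = "paper") -> ClassNBFit:
    """Method-of-moments NB fit, one distribution per OTU column.

    Sample variance uses the unbiased (n-1) denominator; at least two samples
    are required.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 2:
        raise NBModelError("class_counts must be 2-D (samples x OTUs)")
    if counts.shape[0] < 2:
        raise NBModelError("need at least 2 samples per class to fit moments")
    if convention not in ("paper", "nb_marginal"):
        raise NBModelError(f"unknown moment convention {convention!r}")
    mu = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    degenerate = (mu <= 0) | (var <= mu * (1.0 + _UNDERDISPERSION_EPS))
    r = np.ones_like(mu)
    theta = np.ones_like(mu)
    ok = ~degenerate
    if convention == "paper":
        theta[ok] = var[ok] / mu[ok]
        r[ok] = mu[ok] ** 2 / var[ok]
    else:  # marginal NB variance r*theta*(1+theta)
        theta[ok] = var[ok] / mu[ok] - 1.0
        r[ok] = mu[ok] / theta[ok]
    return ClassNBFit(r=r, theta=theta, mean=mu, degenerate=degenerate,
                      convention=convention)


def sample_augmented(
    fit: ClassNBFit, n_aug: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_aug`` synthetic count rows from a fitted class distribution.

    Non-degenerate OTUs use the Gamma-Poisson hierarchy with the fitted
    (r, theta); degenerate OTUs emit zeros (zero-mean) or Poisson(mean) draws.
    """
    if n_aug < 0:
        raise NBModelError("n_aug must be non-negative")
    p = fit.n_otus
    out = np.zeros((n_aug, p), dtype=np.int64)
    if n_aug == 0:
        return out
    ok = ~fit.degenerate
    if ok.any():
        lam = rng.gamma(shape=fit.r[ok], scale=fit.theta[ok], size=(n_aug, int(ok.sum())))
        out[:, ok] = rng.poisson(lam)
    pois = fit.degenerate & (fit.mean > 0)
    if pois.any():
        out[:, pois] = rng.poisson(fit.mean[pois], size=(n_aug, int(pois.sum())))
    return out


def augment_training_set(
    train: OTUTable,
    n_aug_per_class: Mapping[str, int] | str = "match",
    rng: np.random.Generator | None = None,
    convention: str = "paper",
) -> OTUTable:
    """Fit per-class NB distributions on the training rows and append samples.

    With ``"match"`` the number of augmented samples equals the number of
    training samples (each class contributes its own size). Fitting sees only
    the rows of ``train`` — callers must pass the training fold, never the
    full dataset, to keep held-out folds untouched. Augmented rows carry their
    class label and sample ids tagged ``aug_``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labels = train.label_vector()
    classes = sorted(set(labels))
    counts_per_class = {c: int((labels == c).sum()) for c in classes}
    if n_aug_per_class == "match":
        n_aug = dict(counts_per_class)
    elif isinstance(n_aug_per_class, str):
        raise NBModelError(f"unknown augmentation size rule {n_aug_per_class!r}")
    else:
        n_aug = {c: int(n_aug_per_class.get(c, 0)) for c in classes}
        if any(v < 0 for v in n_aug.values()):
            raise NBModelError("augmented sample counts must be non-negative")
    for c in classes:
        if counts_per_class[c] < 2:
            raise NBModelError(f"class {c!r} has fewer than 2 training samples")

    new_blocks, new_ids, new_labels = [], [], {}
    for c in classes:
        fit = fit_nb_moments(train.counts[labels == c], convention=convention)
        rows = sample_augmented(fit, n_aug[c], rng)
        new_blocks.append(rows)
        for i in range(rows.shape[0]):
            sid = f"aug_{c}_{i:04d}"
            new_ids.append(sid)
            new_labels[sid] = c

    counts = np.vstack([train.counts] + new_blocks)
    sample_ids = list(train.sample_ids) + new_ids
    merged_labels = dict(train.labels)
    merged_labels.update(new_labels)
    return OTUTable(counts, sample_ids, list(train.otu_ids), train.taxonomy,
                    merged_labels)
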