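"""Synthetic microbial count data from per-class negative-binomial profiles.

Counts are drawn through the Gamma-Poisson hierarchy: a per-OTU Poisson rate
lambda ~ Gamma(shape r, scale theta), then count ~ Poisson(lambda), whose
marginal is negative binomial with success probability p = theta/(1+theta).
Small shape r at fixed mean gives the heavy zero inflation characteristic of
16S count tables; r -> infinity recovers the Poisson.

Measurement noise is layered on as three independent per-cell channels:

* type 1 — a true zero is reported as a small positive count (spurious reads);
* type 2 — a true non-zero drops out to zero;
* type 3 — a true non-zero is reported with a fluctuation, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .io_config import OTUTable

__all__ = [
    "ClassProfile",
    "ErrorSpec",
    "SimulationConfig",
    "generate_class_profiles",
    "sample_nb",
    "nb_pmf",
    "inject_errors",
    "simulate_dataset",
]


class SimulationError(ValueError):
    pass


@dataclass
class ClassProfile:
    """Per-class mean/dispersion structure over the p OTUs.

    OTUs come in contiguous blocks; every OTU in block b shares the block's
    NB shape (dispersion) ``block_dispersions[b]`` while keeping its own mean.
    """

    class_id: str
    otu_means: np.ndarray
    block_sizes: Sequence[int]
    block_dispersions: Sequence[float]

    def __post_init__(self) -> None:
        self.otu_means = np.asarray(self.otu_means, dtype=float)
        self.block_sizes = [int(m) for m in self.block_sizes]
        self.block_dispersions = [float(r) for r in self.block_dispersions]
        if len(self.block_sizes) != len(self.block_dispersions):
            raise SimulationError("block_sizes and block_dispersions differ in length")
        if any(m <= 0 for m in self.block_sizes):
            raise SimulationError("block sizes must be positive")
        if sum(self.block_sizes) != self.otu_means.size:
            raise SimulationError(
                f"block sizes sum to {sum(self.block_sizes)}, "
                f"but profile has {self.otu_means.size} OTUs"
            )
        if any(r <= 0 for r in self.block_dispersions):
            raise SimulationError("dispersions must be positive")
        if np.any(self.otu_means < 0):
            raise SimulationError("OTU means must be non-negative")

    def dispersion_vector(self) -> np.ndarray:
        """Per-OTU shape r, each OTU inheriting its block's dispersion."""
        return np.repeat(self.block_dispersions, self.block_sizes).astype(float)


@dataclass
class ErrorSpec:
    """Per-cell measurement-error probabilities and channel settings.

    ``t1_count_mean`` is the mean of the replacement count a type-1 error
    writes into a true zero (drawn as 1 + Poisson(t1_count_mean - 1), so small
    means give mostly single spurious reads). ``t3_noise_scale`` scales the
    type-3 fluctuation: the reported count is max(1, d + round(N(0, scale*d))),
    a multiplicative-width perturbation clamped away from zero so a type-3
    error can never masquerade as a type-2 dropout.
    """

    e1: float = 0.0
    e2: float = 0.0
    e3: float = 0.0
    t1_count_mean: float = 1.0
    t3_noise_scale: float = 0.5

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "e3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.e2 + self.e3 > 1.0 + 1e-12:
            raise SimulationError("e2 + e3 may not exceed 1 (one error per cell)")
        if self.t1_count_mean < 1.0:
            raise SimulationError("t1_count_mean must be >= 1")
        if self.t3_noise_scale <= 0:
            raise SimulationError("t3_noise_scale must be positive")


@dataclass
class SimulationConfig:
    n_classes: int = 8
    samples_per_class: int = 100
    n_otus: int = 100
    block_sizes: Sequence[int] = (30, 40, 30)
    block_dispersions: Sequence[float] = (0.1, 1.0, 10.0)
    mean_range: tuple[float, float] = (0.1, 100.0)
    error_spec: ErrorSpec = field(default_factory=ErrorSpec)
    profiles: Sequence[ClassProfile] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise SimulationError("need at least 2 classes")
        if self.samples_per_class < 1:
            raise SimulationError("need at least 1 sample per class")
        if self.n_otus < 1:
            raise SimulationError("need at least 1 OTU")


def generate_class_profiles(
    n_classes: int,
    block_sizes: Sequence[int],
    block_dispersions: Sequence[float],
    rng: np.random.Generator,
    mean_range: tuple[float, float] = (0.1, 100.0),
) -> list[ClassProfile]:
    """Draw one random microbiome profile per class.

    Per-OTU means are drawn independently per class, log-uniformly over
    ``mean_range`` so they span orders of magnitude (keeping sparsity and
    abundance structure realistic); distinct draws make the classes
    distinguishable. Each OTU inherits the dispersion of its block.
    """
    lo, hi = mean_range
    if not 0 < lo <= hi:
        raise SimulationError("mean_range must satisfy 0 < lo <= hi")
    p = sum(int(m) for m in block_sizes)
    profiles = []
    for c in range(n_classes):
        means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=p))
        profiles.append(
            ClassProfile(f"class_{c}", means, list(block_sizes), list(block_dispersions))
        )
    return profiles


def sample_nb(
    r: float, theta: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw NB counts through the Gamma-Poisson hierarchy.

    lambda ~ Gamma(shape=r, scale=theta) then count ~ Poisson(lambda); the
    marginal mean is r*theta and p = theta/(1+theta).
    """
    if r <= 0 or theta <= 0:
        raise SimulationError("r and theta must be positive")
    lam = rng.gamma(shape=r, scale=theta, size=size)
    return rng.poisson(lam)


def nb_pmf(v, r: float, p_success: float):
    """Negative-binomial mass Gamma(r+v)/(v! Gamma(r)) p^v (1-p)^r.

    Evaluated in log space for stability; v may be a scalar or array of
    non-negative integers.
    """
    if not 0.0 < p_success < 1.0:
        raise SimulationError("p_success must lie strictly in (0, 1)")
    if r <= 0:
        raise SimulationError("r must be positive")
    v_arr = np.asarray(v)
    if np.any(v_arr < 0) or not np.all(np.equal(np.mod(v_arr, 1), 0)):
        raise SimulationError("v must be a non-negative integer")
    v_arr = v_arr.astype(float)
    logpmf = (
        gammaln(r + v_arr)
        - gammaln(v_arr + 1.0)
        - gammaln(r)
        + v_arr * np.log(p_success)
        + r * np.log1p(-p_success)
    )
    out = np.exp(logpmf)
    return out if out.ndim else float(out)


def inject_errors(
    counts: np.ndarray, spec: ErrorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Apply the three measurement-error channels independently per cell.

    True zeros: with probability e1 become 1 + Poisson(t1_count_mean - 1).
    True non-zeros: a single uniform draw routes the cell to dropout (e2,
    set to zero) or fluctuation (e3, perturbed but clamped >= 1), so each
    cell suffers at most one error.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise SimulationError("counts must be non-negative")
    out = counts.astype(np.int64).copy()
    zero = out == 0
    # type 1: spurious positive counts on true zeros
    hit1 = zero & (rng.random(out.shape) < spec.e1)
    n1 = int(hit1.sum())
    if n1:
        out[hit1] = 1 + rng.poisson(spec.t1_count_mean - 1.0, size=n1)
    # types 2 and 3 share one uniform draw over the original non-zeros
    u = rng.random(out.shape)
    hit2 = ~zero & (u < spec.e2)
    hit3 = ~zero & (u >= spec.e2) & (u < spec.e2 + spec.e3)
    out[hit2] = 0
    n3 = int(hit3.sum())
    if n3:
        d = out[hit3].astype(float)
        noise = rng.normal(0.0, spec.t3_noise_scale * d)
        out[hit3] = np.maximum(1, d + np.rint(noise)).astype(np.int64)
    return out


def simulate_dataset(config: SimulationConfig) -> OTUTable:
    """Generate a labeled synthetic count table.

    Per class, counts are drawn OTU-wise from the class profile through the
    Gamma-Poisson hierarchy and then passed through :func:`inject_errors`.
    Classes are balanced at ``samples_per_class`` rows each.
    """
    rng = np.random.default_rng(config.seed)
    profiles = config.profiles
    if profiles is None:
        profiles = generate_class_profiles(
            config.n_classes,
            config.block_sizes,
            config.block_dispersions,
            rng,
            config.mean_range,
        )
    if len(profiles) != config.n_classes:
        raise SimulationError("one profile required per class")
    d = config.samples_per_class
    blocks, sample_ids, labels = [], [], {}
    for profile in profiles:
        r = profile.dispersion_vector()
        theta = profile.otu_means / r  # mean = r * theta
        lam = rng.gamma(shape=r, scale=theta, size=(d, r.size))
        true_counts = rng.poisson(lam)
        observed = inject_errors(true_counts, config.error_spec, rng)
        blocks.append(observed)
        for i in range(d):
            sid = f"{profile.class_id}_s{i:04d}"
            sample_ids.append(sid)
            labels[sid] = profile.class_id
    counts = np.vstack(blocks)
    otu_ids = [f"otu_{j:04d}" for j in range(counts.shape[1])]
    return OTUTable(counts, sample_ids, otu_ids, taxonomy=None, labels=labels)
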