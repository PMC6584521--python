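"""Prevalence filtering, relative-abundance normalization and [0,1] rescaling.

The feature pipeline is label-blind: none of these operations ever consult
class labels, so running the filter once per dataset (before cross-validation)
cannot leak information. Min-max rescaling, in contrast, is stateful — its
per-OTU minima/maxima must be learned on the training fold only and applied
(with clipping) to held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_config import OTUTable

__all__ = [
    "AbundanceMatrix",
    "MinMaxState",
    "filter_low_prevalence",
    "to_relative_abundance",
    "fit_rescaler",
    "apply_rescaler",
]


class PreprocessError(ValueError):
    pass


@dataclass
class MinMaxState:
    """Per-OTU minima and maxima learned from training abundances."""

    otu_ids: Sequence[str]
    mins: np.ndarray
    maxs: np.ndarray


@dataclass
class AbundanceMatrix:
    """Real-valued feature matrix in [0,1], samples x (filtered) OTUs."""

    values: np.ndarray
    sample_ids: Sequence[str]
    otu_ids: Sequence[str]
    scaler_state: MinMaxState | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.otu_ids = list(self.otu_ids)
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise PreprocessError("values shape does not match id lists")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise PreprocessError("abundance values must lie in [0, 1]")


def filter_low_prevalence(table: OTUTable, min_prevalence: float = 0.10) -> OTUTable:
    """Drop OTUs observed (count > 0) in fewer than ``min_prevalence`` of samples.

    Retention uses a strict "less than" removal rule: an OTU present in exactly
    the threshold fraction of samples is kept. Column order is preserved.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise PreprocessError("min_prevalence must lie in [0, 1]")
    if table.n_samples == 0:
        return table
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise PreprocessError(
            f"prevalence filter at {min_prevalence:.0%} removed every OTU"
        )
    return table.select_otus(keep)


def to_relative_abundance(table: OTUTable) -> AbundanceMatrix:
    """Normalize each sample's counts by its cumulative count.

    Row i becomes d^i / s^i where s^i is the sample's total count, giving a
    composition vector that sums to 1; this absorbs differences in sequencing
    depth between samples.
    """
    totals = table.counts.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = [table.sample_ids[i] for i in dead[:5]]
        raise PreprocessError(f"samples with zero total count: {names}")
    values = table.counts / totals[:, None]
    return AbundanceMatrix(values, list(table.sample_ids), list(table.otu_ids))


def fit_rescaler(train: AbundanceMatrix) -> MinMaxState:
    """Learn per-OTU min/max from training rows only (row-order invariant)."""
    if train.values.shape[0] == 0:
        raise PreprocessError("cannot fit a rescaler on an empty matrix")
    return MinMaxState(
        otu_ids=list(train.otu_ids),
        mins=train.values.min(axis=0),
        maxs=train.values.max(axis=0),
    )


def apply_rescaler(matrix: AbundanceMatrix, state: MinMaxState) -> AbundanceMatrix:
    """Min-max transform (x - min)/(max - min) per OTU, clipped to [0, 1].

    Constant training columns (max == min) map to 0. Held-out values outside
    the training range are clipped so features stay in [0, 1].
    """
    if list(matrix.otu_ids) != list(state.otu_ids):
        raise PreprocessError("rescaler was fitted on a different OTU set")
    span = state.maxs - state.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (matrix.values - state.mins) / safe
    scaled[:, span <= 0] = 0.0
    scaled = np.clip(scaled, 0.0, 1.0)
    return AbundanceMatrix(scaled, list(matrix.sample_ids), list(matrix.otu_ids), state)
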