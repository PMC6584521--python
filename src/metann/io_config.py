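"""Count-table and configuration I/O plus seeded RNG management.

The on-disk layout keeps the count file purely numeric: counts live in a
TSV with a ``sample_id`` index column and one column per OTU; labels and
taxonomy are separate two-column TSVs. Configuration files may be JSON or
YAML (JSON is a YAML subset, so one loader serves both).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OTUTable",
    "RunConfig",
    "read_otu_table",
    "write_otu_table",
    "load_config",
    "spawn_rngs",
]


class OTUTableError(ValueError):
    """Raised when a count table or its companion files are inconsistent."""


@dataclass
class OTUTable:
    """An integer OTU count matrix with sample/OTU identifiers.

    ``counts`` is oriented samples x OTUs (n x p). ``taxonomy`` maps an OTU id
    to its semicolon-joined rank string (phylum;class;order;family;genus);
    ``labels`` maps a sample id to its class label. Both are optional.
    """

    counts: np.ndarray
    sample_ids: Sequence[str]
    otu_ids: Sequence[str]
    taxonomy: Mapping[str, str] | None = None
    labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise OTUTableError("counts must be a 2-D matrix")
        self.sample_ids = list(self.sample_ids)
        self.otu_ids = list(self.otu_ids)
        n, p = self.counts.shape
        if len(self.sample_ids) != n:
            raise OTUTableError(
                f"{len(self.sample_ids)} sample ids for {n} count rows"
            )
        if len(self.otu_ids) != p:
            raise OTUTableError(f"{len(self.otu_ids)} OTU ids for {p} count columns")
        if len(set(self.sample_ids)) != n:
            raise OTUTableError("duplicate sample ids")
        if len(set(self.otu_ids)) != p:
            raise OTUTableError("duplicate OTU ids")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                    raise OTUTableError("counts must be integral")
                self.counts = self.counts.astype(np.int64)
            if np.any(self.counts < 0):
                raise OTUTableError("counts must be non-negative")
        else:
            self.counts = self.counts.astype(np.int64)
        if self.labels is not None:
            self.labels = dict(self.labels)
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise OTUTableError(f"samples without a label: {missing[:5]}")
            unknown = set(self.labels) - set(self.sample_ids)
            if unknown:
                raise OTUTableError(
                    f"labels reference unknown samples: {sorted(unknown)[:5]}"
                )
        if self.taxonomy is not None:
            self.taxonomy = dict(self.taxonomy)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def label_vector(self) -> np.ndarray:
        """Per-sample labels in row order (requires labels)."""
        if self.labels is None:
            raise OTUTableError("table has no labels")
        return np.asarray([self.labels[s] for s in self.sample_ids])

    def select_samples(self, index: Sequence[int]) -> "OTUTable":
        """Row subset (new table); labels/taxonomy carried along."""
        index = np.asarray(index)
        ids = [self.sample_ids[i] for i in index]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in ids}
        return OTUTable(self.counts[index], ids, list(self.otu_ids), self.taxonomy, labels)

    def select_otus(self, mask: Sequence[bool]) -> "OTUTable":
        """Column subset by boolean mask, order preserved."""
        mask = np.asarray(mask, dtype=bool)
        ids = [o for o, keep in zip(self.otu_ids, mask) if keep]
        tax = None
        if self.taxonomy is not None:
            tax = {o: t for o, t in self.taxonomy.items() if o in set(ids)}
        return OTUTable(self.counts[:, mask], list(self.sample_ids), ids, tax, self.labels)


def read_otu_table(
    count_path: str | os.PathLike,
    label_path: str | os.PathLike | None = None,
    taxonomy_path: str | os.PathLike | None = None,
    transposed: bool = False,
) -> OTUTable:
    """Read a count TSV (header of OTU ids, first column sample ids).

    ``transposed=True`` accepts the OTUs-as-rows dialect common in published
    OTU tables and flips it to samples x OTUs.
    """
    df = pd.read_csv(count_path, sep="\t", index_col=0, dtype=str)
    if transposed:
        df = df.T
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                as_float = float(raw)
            except (TypeError, ValueError):
                raise OTUTableError(
                    f"non-numeric count {raw!r} at sample {df.index[i]!r}, OTU {col!r}"
                ) from None
            if as_float != int(as_float):
                raise OTUTableError(
                    f"non-integer count {raw!r} at sample {df.index[i]!r}, OTU {col!r}"
                )
            if as_float < 0:
                raise OTUTableError(
                    f"negative count {raw!r} at sample {df.index[i]!r}, OTU {col!r}"
                )
            values[i, j] = int(as_float)
    labels = None
    if label_path is not None:
        lab = pd.read_csv(label_path, sep="\t", dtype=str)
        if lab.shape[1] != 2:
            raise OTUTableError("label file must have two columns: sample_id, label")
        labels = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
        if tax.shape[1] != 2:
            raise OTUTableError("taxonomy file must have two columns: otu_id, taxonomy")
        taxonomy = dict(zip(tax.iloc[:, 0], tax.iloc[:, 1]))
    return OTUTable(values, list(df.index), list(df.columns), taxonomy, labels)


def write_otu_table(
    table: OTUTable,
    count_path: str | os.PathLike,
    label_path: str | os.PathLike | None = None,
    taxonomy_path: str | os.PathLike | None = None,
) -> None:
    """Write the table so that :func:`read_otu_table` inverts it bit-exactly."""
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.otu_ids)
    df.index.name = "sample_id"
    df.to_csv(count_path, sep="\t")
    if label_path is not None:
        if table.labels is None:
            raise OTUTableError("table has no labels to write")
        pd.DataFrame(
            {"sample_id": table.sample_ids,
             "label": [table.labels[s] for s in table.sample_ids]}
        ).to_csv(label_path, sep="\t", index=False)
    if taxonomy_path is not None:
        if table.taxonomy is None:
            raise OTUTableError("table has no taxonomy to write")
        pd.DataFrame(
            {"otu_id": list(table.taxonomy), "taxonomy": list(table.taxonomy.values())}
        ).to_csv(taxonomy_path, sep="\t", index=False)


class ConfigError(ValueError):
    """Raised for malformed or out-of-range run configuration."""


@dataclass
class RunConfig:
    """Benchmark-run settings.

    ``dropout_q`` is the input-dropout rate used by the neural models (0.5 by
    default, the value known to work well across networks and tasks);
    ``augment`` toggles training-fold NB augmentation. ``models`` holds nested
    per-model hyperparameter mappings consumed by the benchmark harness.
    """

    seed: int = 0
    n_folds: int = 10
    n_runs: int = 5
    augment: bool = False
    dropout_q: float = 0.5
    min_prevalence: float = 0.10
    rescale: bool = True
    models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be at least 2")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be at least 1")
        if not 0.0 <= self.dropout_q < 1.0:
            raise ConfigError("dropout_q must lie in [0, 1)")
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ConfigError("min_prevalence must lie in [0, 1]")


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a JSON or YAML run configuration, filling defaults.

    Unknown top-level keys are rejected rather than silently ignored so that
    typos in a config file surface immediately.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically derive ``n`` independent generators from a root seed.

    Children are spawned through :class:`numpy.random.SeedSequence`, so any
    child stream is reproducible on its own given (seed, index).
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
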