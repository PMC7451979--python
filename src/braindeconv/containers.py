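"""Core data containers shared by every stage of the pipeline.

All containers are thin wrappers around :class:`pandas.DataFrame` that add
the metadata the pipeline needs to stay honest about units and provenance:
an expression matrix knows whether it holds raw counts or log2 CPM, a
proportion matrix knows whether it was estimated (exact simplex per sample)
or measured (column sums only approximately one, as with independent
per-cell-type immunostaining), and a marker set carries the fold-change /
FDR evidence behind each gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReferenceDataset",
    "MarkerSet",
    "ProportionMatrix",
    "SingleCellPopulation",
    "NoiseModel",
    "SimulationTruth",
    "SIMPLEX_ATOL",
]

#: numerical tolerance on per-sample proportion sums for estimated tables
SIMPLEX_ATOL = 1e-9

_EXPR_SCALES = ("counts", "cpm", "log2cpm", "linear")


def _check_frame(data: pd.DataFrame, what: str) -> pd.DataFrame:
    if data.empty:
        raise ValueError(f"{what} is empty")
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"{what} has duplicate row identifiers: {dups[:5]}")
    if data.columns.has_duplicates:
        dups = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValueError(f"{what} has duplicate column identifiers: {dups[:5]}")
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{what} contains non-numeric cells")
    return data


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit scale tag.

    ``scale`` is one of ``counts`` (raw or simulated read counts), ``cpm``
    (library-size normalised), ``log2cpm`` (log2(CPM + pseudo-count)) or
    ``linear`` (non-count linear units, e.g. averaged single-cell profiles).
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        _check_frame(self.data, "expression matrix")
        if self.scale not in _EXPR_SCALES:
            raise ValueError(f"unknown expression scale {self.scale!r}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def is_log(self) -> bool:
        return self.scale == "log2cpm"

    def to_linear(self, pseudo_count: float = 1.0) -> "ExpressionMatrix":
        """Undo a log2 transform if present; linear-scale input is returned as is."""
        if not self.is_log:
            return self
        lin = np.maximum(np.exp2(self.data) - pseudo_count, 0.0)
        return ExpressionMatrix(lin, scale="linear")


@dataclass
class ReferenceDataset:
    """Gene x reference-sample matrix with per-sample cell-type labels."""

    data: pd.DataFrame
    labels: pd.Series  # sample -> cell-type name
    scale: str = "counts"

    def __post_init__(self) -> None:
        _check_frame(self.data, "reference matrix")
        self.labels = pd.Series(self.labels)
        missing = self.data.columns.difference(self.labels.index)
        if len(missing):
            raise ValueError(f"reference samples without labels: {list(missing)[:5]}")
        self.labels = self.labels.loc[self.data.columns]
        if self.scale not in _EXPR_SCALES:
            raise ValueError(f"unknown reference scale {self.scale!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.labels))

    def samples_of(self, cell_type: str) -> pd.Index:
        return self.labels.index[self.labels == cell_type]

    def replicate_counts(self) -> pd.Series:
        return self.labels.value_counts()


class MarkerSet(Mapping[str, list]):
    """Ordered mapping cell type -> ranked marker gene list.

    ``metadata`` optionally records, per (cell_type, gene), the log2
    fold-change and BH-adjusted FDR that justified the gene's selection.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        metadata: pd.DataFrame | None = None,
    ) -> None:
        self._sets: dict[str, list[str]] = {}
        for ct, genes in sets.items():
            genes = list(genes)
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate genes in marker list for {ct!r}")
            self._sets[str(ct)] = genes
        self.metadata = metadata

    def __getitem__(self, key: str) -> list[str]:
        return self._sets[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def cell_types(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self._sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def subset(self, cell_types: Sequence[str]) -> "MarkerSet":
        return MarkerSet({ct: self._sets[ct] for ct in cell_types}, self.metadata)

    def __repr__(self) -> str:
        sizes = ", ".join(f"{ct}: {len(g)}" for ct, g in self._sets.items())
        return f"MarkerSet({sizes})"


@dataclass
class ProportionMatrix:
    """Cell type x sample proportion table.

    ``kind`` distinguishes three provenances with different invariants:

    - ``estimated``: produced by a deconvolution method; entries >= 0 and
      every column sums to exactly one (within :data:`SIMPLEX_ATOL`).
    - ``true``: simulation ground truth; same exact-simplex invariant.
    - ``measured``: IHC-like independent per-type measurements; entries
      >= 0 but column sums only scatter around one.
    """

    data: pd.DataFrame
    kind: str = "estimated"

    def __post_init__(self) -> None:
        _check_frame(self.data, "proportion matrix")
        if self.kind not in ("estimated", "true", "measured"):
            raise ValueError(f"unknown proportion kind {self.kind!r}")
        values = self.data.to_numpy(dtype=float)
        if (values < -SIMPLEX_ATOL).any():
            raise ValueError("proportion matrix has negative entries")
        if self.kind in ("estimated", "true"):
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.data.columns[~np.isclose(sums, 1.0, atol=1e-6)]
                raise ValueError(
                    f"{self.kind} proportions must sum to 1 per sample; "
                    f"violated for samples {list(bad)[:5]}"
                )

    @property
    def cell_types(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class SingleCellPopulation:
    """A labelled single-cell count population with planted marker truth.

    ``type_means`` holds the expected expression of each gene in each cell
    type; planted markers for type k satisfy
    ``type_means[g, k] >= fold_change * max over other types``.
    """

    counts: pd.DataFrame  # gene x cell, non-negative integers
    cell_labels: pd.Series  # cell -> cell-type name
    type_means: pd.DataFrame  # gene x cell-type
    marker_truth: dict[str, list[str]]

    def __post_init__(self) -> None:
        _check_frame(self.counts, "single-cell counts")
        self.cell_labels = pd.Series(self.cell_labels).loc[self.counts.columns]
        unknown = set(self.cell_labels) - set(self.type_means.columns)
        if unknown:
            raise ValueError(f"cell labels missing from type_means: {sorted(unknown)}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("single-cell counts must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.type_means.columns)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def type_frequencies(self) -> pd.Series:
        freq = self.cell_labels.value_counts(normalize=True)
        return freq.reindex(self.cell_types, fill_value=0.0)


@dataclass
class NoiseModel:
    """Negative-binomial read-count noise: variance = mu + phi * mu^2.

    ``dispersion`` (phi) of zero degenerates to Poisson noise.
    ``pseudo_count`` is the offset used before any log transform downstream.
    """

    dispersion: float
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class SimulationTruth:
    """Ground-truth record emitted alongside simulated datasets."""

    proportions: ProportionMatrix
    eqtl_effects: list[tuple[str, str, str, float]] = field(default_factory=list)
    phenotype_effects: dict = field(default_factory=dict)


def warn_once(message: str) -> None:
    warnings.warn(message, UserWarning, stacklevel=3)
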