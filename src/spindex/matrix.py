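"""In-memory containers: count matrices, the two-group design, abundances.

Counts are plain non-negative integer :class:`pandas.DataFrame` objects
(entities x samples) wrapped with a design that assigns every sample to
exactly one of two groups.  Abundances (RPKM) carry a per-cell provenance
flag recording whether the value is the raw RPKM or the replacement floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Design", "CountMatrix", "ExonCountMatrix", "AbundanceMatrix"]


class DesignError(ValueError):
    pass


class CountError(ValueError):
    pass


@dataclass(frozen=True)
class Design:
    """Sample-to-group assignment for a two-group comparison.

    ``group_a`` is the numerator group of fold changes (the mutant genotype
    in the motivating study); ``group_b`` the denominator (control).
    """

    groups: pd.Series  # index: sample_id, values: group label
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        labels = set(self.groups.unique())
        if labels != {self.group_a, self.group_b}:
            raise DesignError(
                f"design must contain exactly the two groups "
                f"{self.group_a!r}, {self.group_b!r}; found {sorted(labels)}"
            )
        if self.groups.index.duplicated().any():
            raise DesignError("duplicate sample ids in design")

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def samples_a(self) -> list[str]:
        return self.samples_in(self.group_a)

    @property
    def samples_b(self) -> list[str]:
        return self.samples_in(self.group_b)


def _validate_counts(counts: pd.DataFrame, design: Design) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise CountError(f"duplicate entity ids: {dups[:5]}")
    missing = [s for s in counts.columns if s not in design.groups.index]
    if missing:
        raise CountError(f"samples absent from the sample sheet: {missing}")
    arr = counts.to_numpy()
    if arr.size == 0:
        counts = counts.astype(np.int64)
        arr = counts.to_numpy()
    elif not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise CountError("counts must be integral")
        counts = counts.round().astype(np.int64)
        arr = counts.to_numpy()
    if (arr < 0).any():
        raise CountError("counts must be non-negative")
    # keep sample order as given by the design
    return counts.loc[:, [s for s in design.samples if s in counts.columns]]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer read counts, entities x samples, plus design."""

    counts: pd.DataFrame
    design: Design

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _validate_counts(self.counts, self.design))

    @property
    def entities(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts over all entities in this matrix."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ExonCountMatrix:
    """Exon-level counts with an exon -> gene mapping."""

    counts: pd.DataFrame  # index: exon_id
    gene_of: pd.Series  # index: exon_id, values: gene_id
    design: Design

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _validate_counts(self.counts, self.design))
        if not self.counts.index.isin(self.gene_of.index).all():
            orphans = self.counts.index[~self.counts.index.isin(self.gene_of.index)]
            raise CountError(
                f"exons with no gene assignment: {orphans[:5].tolist()}"
            )
        object.__setattr__(self, "gene_of", self.gene_of.loc[self.counts.index])

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def gene_counts(self) -> CountMatrix:
        """Gene-level counts as the sum of each gene's exon counts."""
        summed = self.counts.groupby(self.gene_of, sort=True).sum()
        summed.index.name = "gene_id"
        return CountMatrix(summed, self.design)

    def as_count_matrix(self) -> CountMatrix:
        return CountMatrix(self.counts, self.design)


RAW = "raw"
FLOORED = "floored"


@dataclass(frozen=True)
class AbundanceMatrix:
    """RPKM values after replacement, with per-cell provenance flags.

    ``floored`` is a boolean frame aligned with ``values``; True marks cells
    whose raw count was at or below the replacement floor and whose value is
    therefore the across-sample average RPKM-equivalent of ``k_floor`` reads.
    """

    values: pd.DataFrame
    floored: pd.DataFrame
    k_floor: int
    lengths: pd.Series = field(default=None)
    library_sizes: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.floored.index) or list(
            self.values.columns
        ) != list(self.floored.columns):
            raise CountError("values and floored flags are misaligned")
        if (self.values.to_numpy() < 0).any():
            raise CountError("RPKM values must be non-negative")

    def flags(self) -> pd.DataFrame:
        """Per-cell string flags ('raw' / 'floored')."""
        return self.floored.map(lambda b: FLOORED if b else RAW)
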