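"""In-memory containers for expression data and ortholog maps.

The analysis manipulates three flavours of gene x tissue matrix:

* :class:`ExpressionMatrix` -- non-negative intensities on a linear scale
  (the absolute expression levels ``x^A``),
* :class:`RelativeMatrix` -- each gene's row divided by its row sum
  (relative expression ``x^R``; rows sum to one),
* :class:`BinaryMatrix` -- presence/absence calls from thresholding each
  gene at its own across-tissue mean (``x^B``).

All three wrap a :class:`pandas.DataFrame` whose index holds the gene
identifiers and whose columns hold the tissue labels, plus a ``species``
tag.  Construction validates the container's invariants once so downstream
code can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "RelativeMatrix",
    "BinaryMatrix",
    "OrthologPairSet",
]


def _check_axes(data: pd.DataFrame) -> None:
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
    if data.columns.has_duplicates:
        dups = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate tissue labels: {dups[:5]}")
    if data.shape[1] < 2:
        raise ValidationError("at least two tissues are required")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x tissue intensities for one species, linear scale.

    Parameters
    ----------
    data
        Genes in rows (index = gene ids), tissues in columns.  Entries must
        be finite and non-negative, and every gene must be detected in at
        least one tissue (a strictly positive entry), which the relative
        transform requires.
    species
        Free-form species tag carried through the pipeline.
    """

    data: pd.DataFrame
    species: str
    scale: str = "linear"

    def __post_init__(self) -> None:
        _check_axes(self.data)
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError(f"non-finite intensities in species {self.species!r}")
        if (values < 0).any():
            raise ValidationError(f"negative intensities in species {self.species!r}")
        rowsum = values.sum(axis=1)
        if (rowsum <= 0).any():
            bad = self.data.index[rowsum <= 0][0]
            raise ValidationError(
                f"gene {bad!r} has no positive intensity in any tissue"
            )
        if self.scale != "linear":
            raise ValidationError("ExpressionMatrix holds linear-scale intensities")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def tissue_labels(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RelativeMatrix:
    """Relative expression: every gene row rescaled to sum to one."""

    data: pd.DataFrame
    species: str

    def __post_init__(self) -> None:
        _check_axes(self.data)
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any() or (values > 1).any():
            raise ValidationError("relative expression must lie in [0, 1]")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("relative-expression rows must sum to 1")

    gene_ids = ExpressionMatrix.gene_ids
    tissue_labels = ExpressionMatrix.tissue_labels
    values = ExpressionMatrix.values
    n_genes = ExpressionMatrix.n_genes
    n_tissues = ExpressionMatrix.n_tissues


@dataclass(frozen=True)
class BinaryMatrix:
    """Presence/absence expression calls (0/1 entries).

    A row of all zeros cannot arise from mean-thresholding (the row maximum
    is always >= the row mean), and is rejected here.
    """

    data: pd.DataFrame
    species: str

    def __post_init__(self) -> None:
        _check_axes(self.data)
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("binary matrix entries must be 0 or 1")
        if (values.sum(axis=1) == 0).any():
            bad = self.data.index[values.sum(axis=1) == 0][0]
            raise ValidationError(f"gene {bad!r} has an all-zero binary row")

    gene_ids = ExpressionMatrix.gene_ids
    tissue_labels = ExpressionMatrix.tissue_labels
    n_genes = ExpressionMatrix.n_genes
    n_tissues = ExpressionMatrix.n_tissues

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)


@dataclass(frozen=True)
class OrthologPairSet:
    """One-to-one mapping between two species' gene identifiers.

    ``species1_ids[k]`` is paired with ``species2_ids[k]``.  Each identifier
    may appear at most once per column (one-to-one orthology).
    """

    species1_ids: tuple = field()
    species2_ids: tuple = field()

    def __init__(self, species1_ids, species2_ids) -> None:
        a = tuple(str(x) for x in species1_ids)
        b = tuple(str(x) for x in species2_ids)
        if len(a) != len(b):
            raise ValidationError("ortholog columns differ in length")
        if len(a) == 0:
            raise ValidationError("empty ortholog pair set")
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValidationError("ortholog mapping is not one-to-one")
        object.__setattr__(self, "species1_ids", a)
        object.__setattr__(self, "species2_ids", b)

    def __len__(self) -> int:
        return len(self.species1_ids)

    def __iter__(self):
        return iter(zip(self.species1_ids, self.species2_ids))

    def as_set(self) -> set:
        return set(zip(self.species1_ids, self.species2_ids))
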