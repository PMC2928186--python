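"""Per-gene expression transforms: relative, binary, and profile entropy.

Relative expression divides each gene's intensities by their across-tissue
sum, so that profiles become comparable between species whose platforms
measure on different absolute scales.  The binary transform thresholds
each gene at its own across-tissue mean, turning tissue-specific genes
into sparse 0/1 vectors and housekeeping genes into nearly-all-one
vectors.  Profile entropy is the Shannon entropy (base 2) of the relative
row: 0 for a gene expressed in a single tissue, log2(T) for a perfectly
uniform gene over T tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BinaryMatrix, ExpressionMatrix, RelativeMatrix
from .errors import ValidationError

__all__ = ["to_relative", "to_binary", "gene_entropy"]


def to_relative(mat: ExpressionMatrix) -> RelativeMatrix:
    """Relative expression: divide every gene row by its row sum.

    Raises :class:`ValidationError` naming the offending gene if any row
    sums to zero (no detected expression).  Scale-invariant: multiplying a
    row by any positive constant leaves the output unchanged.
    """
    values = mat.values
    rowsum = values.sum(axis=1)
    if (rowsum <= 0).any():
        bad = mat.gene_ids[rowsum <= 0][0]
        raise ValidationError(f"gene {bad!r}: row sums to zero, relative expression undefined")
    rel = values / rowsum[:, None]
    frame = pd.DataFrame(rel, index=mat.gene_ids, columns=mat.tissue_labels)
    return RelativeMatrix(frame, species=mat.species)


def to_binary(mat: ExpressionMatrix) -> BinaryMatrix:
    """Threshold each gene at its across-tissue mean: 1 iff >= the mean.

    Ties at the mean map to 1, so a perfectly flat (housekeeping-like) row
    becomes all ones rather than all zeros.  Row-wise and independent of
    other genes; scale-invariant under positive row scaling.
    """
    values = mat.values
    mean = values.mean(axis=1)
    binary = (values >= mean[:, None]).astype(np.int8)
    frame = pd.DataFrame(binary, index=mat.gene_ids, columns=mat.tissue_labels)
    return BinaryMatrix(frame, species=mat.species)


def gene_entropy(mat: ExpressionMatrix) -> pd.Series:
    """Shannon entropy (bits) of each gene's relative-expression row.

    With ``p`` the gene's relative row, ``H = -sum_j p_j log2 p_j`` (and
    ``0 log 0 == 0``).  Ranges from 0, for a gene expressed in exactly one
    tissue, to ``log2(n_tissues)`` for uniform expression across all
    tissues.  Returned as a Series indexed by gene id, named ``entropy``.
    """
    rel = to_relative(mat)
    h = stats.entropy(rel.values, base=2, axis=1)
    return pd.Series(h, index=mat.gene_ids, name="entropy")
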