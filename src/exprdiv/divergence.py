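"""Conserved-pair calling against an empirical random-pair null.

Expression evolution is constrained: orthologous gene pairs diverge less,
on average, than random between-species gene pairs.  The null model here
is the empirical distribution of distances between randomly re-paired
genes; an ortholog pair is called conserved when its distance falls at or
below the lower-tail significance threshold of that null (unusually
small distance = unusually conserved profile).  The threshold is the
nearest-rank lower quantile -- the ``ceil(alpha * N)``-th smallest null
distance -- which avoids any interpolation ambiguity.

The module also characterizes called gene sets (mean absolute expression
level, across-tissue variability) and implements the upper-entropy-
quartile gene selection used to probe how "uniform expression" relates
to divergence under different measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .distances import PairDistanceVector
from .errors import ValidationError

__all__ = [
    "NullModel",
    "ConservedPairReport",
    "ContrastSummary",
    "build_null",
    "call_conserved",
    "upper_quartile_entropy_genes",
    "contrast_called_sets",
]


@dataclass(frozen=True)
class NullModel:
    """Empirical null of random-pair distances with a lower-tail threshold."""

    measure: str
    params: dict
    values: np.ndarray  # sorted ascending
    alpha: float
    threshold: float

    @property
    def n(self) -> int:
        return len(self.values)


def build_null(random_distances: PairDistanceVector, alpha: float) -> NullModel:
    """Build the null model at significance level ``alpha``.

    The threshold is the ``ceil(alpha * N)``-th smallest defined random-
    pair distance (nearest-rank, lower tail).  Requires at least
    ``1 / alpha`` defined distances, otherwise the quantile is vacuous.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie strictly between 0 and 1")
    values = np.sort(np.asarray(random_distances.values, dtype=float))
    n = values.size
    n_min = math.ceil(1.0 / alpha)
    if n < n_min:
        raise ValidationError(
            f"need at least {n_min} defined random-pair distances for alpha={alpha:g}, got {n}"
        )
    k = math.ceil(alpha * n)
    return NullModel(
        measure=random_distances.measure,
        params=dict(random_distances.params),
        values=values,
        alpha=float(alpha),
        threshold=float(values[k - 1]),
    )


@dataclass(frozen=True)
class ConservedPairReport:
    """Ortholog pairs called conserved under one measure's null.

    ``expression_by_species`` (present when the raw matrices were
    supplied) holds each called pair's mean absolute -- untransformed --
    expression in each species: level information that every transform
    deliberately erases, but that distinguishes "conserved because flat
    and near background" from "conserved because concertedly expressed".
    """

    measure: str
    params: dict
    alpha: float
    threshold: float
    n_tested: int
    n_excluded: int
    called_ids: tuple
    called_values: np.ndarray
    expression_by_species: pd.DataFrame | None = None

    @property
    def n_called(self) -> int:
        return len(self.called_ids)

    @property
    def called_fraction(self) -> float:
        return self.n_called / self.n_tested if self.n_tested else math.nan


def _mean_expression(mat: ExpressionMatrix, ids) -> np.ndarray:
    idx = mat.gene_ids.get_indexer(list(ids))
    if (idx < 0).any():
        missing = [g for g, i in zip(ids, idx) if i < 0][0]
        raise ValidationError(f"gene {missing!r} not found in matrix {mat.species!r}")
    return mat.values[idx].mean(axis=1)


def call_conserved(
    ortholog_distances: PairDistanceVector,
    null: NullModel,
    matA: ExpressionMatrix | None = None,
    matB: ExpressionMatrix | None = None,
) -> ConservedPairReport:
    """Call ortholog pairs whose distance is at or below the null threshold.

    The boundary is inclusive (``<=``), so a distance exactly equal to
    the threshold is called.  The measure and parameters of the distance
    vector must match those of the null.  Supplying the two raw
    expression matrices adds the per-pair mean absolute expression per
    species to the report.
    """
    if ortholog_distances.measure != null.measure or dict(ortholog_distances.params) != dict(null.params):
        raise ValidationError(
            f"measure mismatch: distances are {ortholog_distances.measure!r}{ortholog_distances.params}, "
            f"null is {null.measure!r}{null.params}"
        )
    values = np.asarray(ortholog_distances.values, dtype=float)
    called_mask = values <= null.threshold
    called_ids = tuple(p for p, ok in zip(ortholog_distances.pair_ids, called_mask) if ok)

    expression = None
    if matA is not None and matB is not None:
        a_ids = [p[0] for p in called_ids]
        b_ids = [p[1] for p in called_ids]
        expression = pd.DataFrame(
            {
                matA.species: _mean_expression(matA, a_ids) if called_ids else [],
                matB.species: _mean_expression(matB, b_ids) if called_ids else [],
            },
            index=pd.MultiIndex.from_tuples(called_ids) if called_ids else None,
        )

    return ConservedPairReport(
        measure=null.measure,
        params=dict(null.params),
        alpha=null.alpha,
        threshold=null.threshold,
        n_tested=ortholog_distances.n_defined,
        n_excluded=ortholog_distances.n_excluded,
        called_ids=called_ids,
        called_values=values[called_mask],
        expression_by_species=expression,
    )


def upper_quartile_entropy_genes(entropy: pd.Series) -> list[str]:
    """The ``ceil(N/4)`` genes with the largest profile entropy.

    Ties at the cut are resolved by stable gene-id order (ascending id
    among equal entropies), so exactly ``ceil(N/4)`` genes are returned.
    Requires at least 4 genes.
    """
    n = len(entropy)
    if n < 4:
        raise ValidationError("need at least 4 genes for a quartile selection")
    k = math.ceil(n / 4)
    frame = pd.DataFrame(
        {"entropy": entropy.to_numpy(), "gene_id": entropy.index.astype(str)}
    )
    ordered = frame.sort_values(by=["entropy", "gene_id"], ascending=[False, True])
    return ordered["gene_id"].iloc[:k].tolist()


@dataclass(frozen=True)
class ContrastSummary:
    """Level/variability contrast between two called gene sets.

    Distributions are over called pairs: (a) the pair's mean absolute
    expression (averaged over tissues and the two species) and (b) the
    across-tissue coefficient of variation (averaged over the two
    species).  ``median_difference`` is median(A) - median(B) of (a).
    The Mann-Whitney U statistic (two-sided) is attached as a purely
    descriptive quantity; the underlying contrast is qualitative and no
    p-value thresholding is performed.
    """

    set_labels: tuple
    n_called: tuple
    mean_expression: tuple          # (array A, array B)
    cv: tuple                       # (array A, array B)
    medians: tuple
    median_difference: float
    mannwhitney_u: float | None
    empty_set: bool = False


def _pair_level_stats(report: ConservedPairReport, matA, matB):
    a_ids = [p[0] for p in report.called_ids]
    b_ids = [p[1] for p in report.called_ids]
    if not a_ids:
        return np.empty(0), np.empty(0)
    rows_a = matA.values[matA.gene_ids.get_indexer(a_ids)]
    rows_b = matB.values[matB.gene_ids.get_indexer(b_ids)]
    mean_expr = (rows_a.mean(axis=1) + rows_b.mean(axis=1)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (
            rows_a.std(axis=1, ddof=0) / rows_a.mean(axis=1)
            + rows_b.std(axis=1, ddof=0) / rows_b.mean(axis=1)
        ) / 2.0
    return mean_expr, cv


def contrast_called_sets(
    reportA: ConservedPairReport,
    reportB: ConservedPairReport,
    matA: ExpressionMatrix,
    matB: ExpressionMatrix,
) -> ContrastSummary:
    """Contrast the expression level and variability of two called sets.

    Uses untransformed intensities: the relative transform erases level,
    and level is exactly what distinguishes the gene populations the two
    measures favour.  With an empty called set the summary is flagged and
    no rank statistic is computed.
    """
    expr_a, cv_a = _pair_level_stats(reportA, matA, matB)
    expr_b, cv_b = _pair_level_stats(reportB, matA, matB)
    empty = expr_a.size == 0 or expr_b.size == 0
    med_a = float(np.median(expr_a)) if expr_a.size else math.nan
    med_b = float(np.median(expr_b)) if expr_b.size else math.nan
    u_stat = None
    if not empty:
        u_stat = float(stats.mannwhitneyu(expr_a, expr_b, alternative="two-sided").statistic)
    return ContrastSummary(
        set_labels=(reportA.measure, reportB.measure),
        n_called=(expr_a.size, expr_b.size),
        mean_expression=(expr_a, expr_b),
        cv=(cv_a, cv_b),
        medians=(med_a, med_b),
        median_difference=med_a - med_b,
        mannwhitney_u=u_stat,
        empty_set=empty,
    )
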