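"""Moment-based selection of generalized-average exponents.

An empirical criterion for picking a well-performing distance out of the
GA family: compute the distance distribution over the gene pairs for each
exponent on a grid, summarize each distribution by its skewness and
(excess) kurtosis, and flag the exponents attaining the extreme values of
those moments.  The binary correlation distance is appended to the scan
as a comparator row, since it competes with the GA family on the same
binary-transformed data.

Conventions: central moments use the biased divide-by-N form, skewness is
``g1 = m3 / m2**1.5`` and kurtosis is reported as excess,
``g2 = m4 / m2**2 - 3``.  The scan compares distributions of equal sample
size, so bias corrections would not change any ranking, but the
convention is fixed (and recorded in run summaries) for reproducibility.
Ties among extremes are reported, never silently broken -- the criterion
is a heuristic, not a test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BinaryMatrix, OrthologPairSet
from .distances import PairDistanceVector, pairwise_distances
from .errors import ValidationError

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "MomentSummary",
    "ExponentScan",
    "distance_moments",
    "scan_ga_exponents",
]

#: Exponent grid spanning the Simpson -> Dice -> max-overlap sweep.
DEFAULT_LAMBDA_GRID = (
    -math.inf, -10.0, -5.0, -2.0, -1.0, 0.0, 1.0, 2.0, 5.0, 10.0, math.inf,
)


@dataclass(frozen=True)
class MomentSummary:
    """Distribution summary for one measure: N, mean, sd, g1, g2.

    ``skewness``/``kurtosis`` are ``None`` when undefined (zero variance).
    """

    measure: str
    params: dict = field(default_factory=dict)
    n: int = 0
    mean: float = math.nan
    sd: float = math.nan
    skewness: float | None = None
    kurtosis: float | None = None

    @property
    def label(self) -> str:
        if self.measure == "ga":
            return f"ga(lam={self.params.get('lam')})"
        return self.measure


def distance_moments(d: PairDistanceVector) -> MomentSummary:
    """Mean, sd, skewness g1 and excess kurtosis g2 of a distance sample.

    Requires at least 4 defined distances.  A zero-variance sample has no
    defined shape statistics; they are flagged absent (``None``).
    """
    values = np.asarray(d.values, dtype=float)
    if values.size < 4:
        raise ValidationError(
            f"need at least 4 defined distances for moment summaries, got {values.size}"
        )
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        skew = kurt = None
    else:
        skew = float(stats.skew(values, bias=True))
        kurt = float(stats.kurtosis(values, fisher=True, bias=True))
    return MomentSummary(
        measure=d.measure,
        params=dict(d.params),
        n=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
    )


@dataclass(frozen=True)
class ExponentScan:
    """Result of a GA exponent scan: per-grid-point summaries + extremes.

    ``selection`` maps each criterion (``min_skewness``, ``min_kurtosis``,
    ``max_kurtosis``) to the list of summary labels attaining it, ties
    included.
    """

    summaries: tuple
    selection: dict

    def summary_for(self, label: str) -> MomentSummary:
        for s in self.summaries:
            if s.label == label:
                return s
        raise KeyError(label)


def _argext(summaries, key, best) -> list[str]:
    vals = [getattr(s, key) for s in summaries]
    defined = [v for v in vals if v is not None]
    if not defined:
        return []
    target = best(defined)
    return [s.label for s, v in zip(summaries, vals) if v == target]


def scan_ga_exponents(
    matA: BinaryMatrix,
    matB: BinaryMatrix,
    pairs: OrthologPairSet,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> ExponentScan:
    """Moment scan of GA distances over ``lambda_grid`` plus binary correlation.

    One :class:`MomentSummary` per grid point (in grid order) with the
    binary-correlation comparator appended last; the selection reports the
    exponents attaining the minimum skewness and the minimum and maximum
    kurtosis, listing ties.
    """
    grid = tuple(float(l) for l in lambda_grid)
    if not grid:
        raise ValidationError("lambda_grid must be non-empty")
    summaries = [
        distance_moments(pairwise_distances(matA, matB, pairs, "ga", {"lam": lam}))
        for lam in grid
    ]
    summaries.append(
        distance_moments(pairwise_distances(matA, matB, pairs, "binary_correlation"))
    )
    selection = {
        "min_skewness": _argext(summaries, "skewness", min),
        "min_kurtosis": _argext(summaries, "kurtosis", min),
        "max_kurtosis": _argext(summaries, "kurtosis", max),
    }
    return ExponentScan(summaries=tuple(summaries), selection=selection)
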