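"""Distance measures between paired expression profiles.

Four measures are implemented:

* ``euclidean`` -- root-sum-of-squares between relative-expression rows,
  sensitive to the uniform component of divergence;
* ``correlation`` -- ``1 - r`` with ``r`` the Pearson coefficient,
  sensitive to concerted (shape) changes and blind to level;
* ``binary_correlation`` -- the same ``1 - r`` applied to mean-thresholded
  0/1 profiles;
* ``ga`` -- the generalized-average family on binary profiles:
  ``d = 1 - X / B_lambda`` where ``X`` is the scalar product of the two
  0/1 vectors and ``B_lambda`` the power mean of exponent ``lambda`` of
  their one-counts ``m`` and ``n``.  The family sweeps through classical
  set-overlap dissimilarities: Simpson at ``lambda -> -inf``
  (``B = min(m, n)``), the cosine/Ochiai form at ``lambda = 0``
  (``B = sqrt(m n)``), Dice at ``lambda = 1`` (``B = (m + n) / 2``) and
  maximum-overlap at ``lambda -> +inf`` (``B = max(m, n)``).

Undefined values (a constant profile for the correlation measures, an
empty binary profile for GA) are returned as ``nan`` and excluded --
never imputed -- by :func:`pairwise_distances`, which records the
exclusion count; an imputed distance would distort the moment statistics
used for distance selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryMatrix, OrthologPairSet, RelativeMatrix
from .errors import ValidationError

__all__ = [
    "euclidean_distance",
    "correlation_distance",
    "binary_correlation_distance",
    "ga_distance",
    "ga_power_mean",
    "pairwise_distances",
    "PairDistanceVector",
    "MEASURES",
]

MEASURES = ("euclidean", "correlation", "binary_correlation", "ga")


def _as_pair(u, v) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.ndim != 1 or v.ndim != 1:
        raise ValidationError("profile vectors must be one-dimensional")
    if u.shape != v.shape:
        raise ValidationError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValidationError("profiles need at least two coordinates")
    return u, v


def euclidean_distance(u, v) -> float:
    """Root-sum-of-squared-differences between two profiles."""
    u, v = _as_pair(u, v)
    return float(np.sqrt(np.sum((u - v) ** 2)))


def correlation_distance(u, v) -> float:
    """``1 - r`` with ``r`` the Pearson correlation; in [0, 2].

    Returns ``nan`` (the undefined marker) when either profile is
    constant: a zero-variance vector has no defined correlation.  Negative
    correlations are kept, so anti-correlated profiles reach distances up
    to 2.
    """
    u, v = _as_pair(u, v)
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.sqrt(np.sum(uc * uc) * np.sum(vc * vc))
    if denom == 0.0:
        return math.nan
    r = float(np.clip(np.sum(uc * vc) / denom, -1.0, 1.0))
    return 1.0 - r


#: Pearson-based distance on binary profiles; identical formula, separate
#: name because the two enter the analysis as distinct measures.
binary_correlation_distance = correlation_distance


def ga_power_mean(m, n, lam: float):
    """Power mean ``((m^lam + n^lam) / 2) ** (1/lam)`` of two one-counts.

    Accepts scalars or arrays and the extended exponents ``-inf`` (min),
    ``0`` (geometric mean, the continuity limit of the power mean) and
    ``+inf`` (max).  Large finite ``|lam|`` is computed in the
    max-factored (resp. min-factored) form so the exponentiation cannot
    overflow: for ``lam > 0``,
    ``B = hi * ((1 + (lo/hi)**lam) / 2) ** (1/lam)``.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if lam == math.inf:
        return np.maximum(m, n)
    if lam == -math.inf:
        return np.minimum(m, n)
    if lam == 0.0:
        return np.sqrt(m * n)
    if lam == 1.0:
        return (m + n) / 2.0
    hi = np.maximum(m, n)
    lo = np.minimum(m, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        if lam > 0:
            ratio = np.where(hi > 0, lo / hi, 1.0)
            out = hi * ((1.0 + ratio**lam) / 2.0) ** (1.0 / lam)
        else:
            ratio = np.where(lo > 0, hi / lo, 1.0)
            out = lo * ((ratio**lam + 1.0) / 2.0) ** (1.0 / lam)
    return out


def _check_binary_vec(u) -> np.ndarray:
    u = np.asarray(u)
    if not np.isin(u, (0, 1)).all():
        raise ValidationError("GA distance requires binary (0/1) vectors")
    return u.astype(float)


def ga_distance(u, v, lam: float) -> float:
    """Generalized-average distance ``1 - X / B_lambda`` between 0/1 vectors.

    ``X`` is the scalar product (shared-one count), ``m`` and ``n`` the
    one-counts, and ``B_lambda`` their power mean of exponent ``lam``
    (any finite real, ``-inf`` or ``+inf``).  Lies in [0, 1] because
    ``X <= min(m, n) <= B_lambda``.  Returns ``nan`` when either vector
    has no ones (the similarity is then indeterminate).
    """
    u, v = _as_pair(_check_binary_vec(u), _check_binary_vec(v))
    m = u.sum()
    n = v.sum()
    if m == 0 or n == 0:
        return math.nan
    x = float(u @ v)
    return 1.0 - x / float(ga_power_mean(m, n, lam))


def _rows_for(mat, ids, side: str) -> np.ndarray:
    idx = mat.gene_ids.get_indexer(list(ids))
    if (idx < 0).any():
        missing = [g for g, i in zip(ids, idx) if i < 0][0]
        raise ValidationError(f"gene {missing!r} not found in {side} matrix")
    return mat.values[idx]


_MEASURE_INPUT = {
    "euclidean": RelativeMatrix,
    "correlation": RelativeMatrix,
    "binary_correlation": BinaryMatrix,
    "ga": BinaryMatrix,
}


@dataclass(frozen=True)
class PairDistanceVector:
    """Per-gene-pair distances under one named measure.

    ``pair_ids`` and ``values`` cover the defined pairs only, in input
    order; pairs whose distance is undefined are listed in
    ``excluded_ids`` and counted by ``n_excluded``.
    """

    measure: str
    params: dict = field(default_factory=dict)
    pair_ids: tuple = ()
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    excluded_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")
        if len(self.pair_ids) != len(self.values):
            raise ValidationError("pair_ids and values length mismatch")

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    @property
    def n_defined(self) -> int:
        return len(self.values)

    def matches(self, other: "PairDistanceVector") -> bool:
        return self.measure == other.measure and self.params == other.params


def pairwise_distances(
    matA,
    matB,
    pairs: OrthologPairSet,
    measure: str,
    params: dict | None = None,
) -> PairDistanceVector:
    """Distance between every pair's two profiles, one value per pair.

    ``matA``/``matB`` must already carry the measure-appropriate transform:
    :class:`RelativeMatrix` for ``euclidean``/``correlation``,
    :class:`BinaryMatrix` for ``binary_correlation``/``ga`` (which takes a
    ``lam`` parameter).  Undefined pairs are excluded and counted, never
    imputed.
    """
    params = dict(params or {})
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}")
    want = _MEASURE_INPUT[measure]
    for side, mat in (("first", matA), ("second", matB)):
        if not isinstance(mat, want):
            raise ValidationError(
                f"measure {measure!r} requires a {want.__name__} as the {side} input"
            )
    rows_a = _rows_for(matA, pairs.species1_ids, "species-1")
    rows_b = _rows_for(matB, pairs.species2_ids, "species-2")

    if measure == "euclidean":
        d = np.sqrt(((rows_a - rows_b) ** 2).sum(axis=1))
    elif measure in ("correlation", "binary_correlation"):
        a = rows_a - rows_a.mean(axis=1, keepdims=True)
        b = rows_b - rows_b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((a * b).sum(axis=1) / denom, -1.0, 1.0)
        d = np.where(denom > 0, 1.0 - r, np.nan)
    else:  # ga
        if "lam" not in params:
            raise ValidationError("measure 'ga' requires a 'lam' parameter")
        lam = float(params["lam"])
        m = rows_a.sum(axis=1).astype(float)
        n = rows_b.sum(axis=1).astype(float)
        x = (rows_a * rows_b).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - x / ga_power_mean(m, n, lam)
        d = np.where((m > 0) & (n > 0), d, np.nan)

    defined = ~np.isnan(d)
    all_ids = tuple(zip(pairs.species1_ids, pairs.species2_ids))
    return PairDistanceVector(
        measure=measure,
        params=params,
        pair_ids=tuple(p for p, ok in zip(all_ids, defined) if ok),
        values=np.asarray(d[defined], dtype=float),
        excluded_ids=tuple(p for p, ok in zip(all_ids, defined) if not ok),
    )
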