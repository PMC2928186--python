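"""Paired two-species expression simulator with known ground truth.

The generator produces two gene x tissue intensity matrices (one per
species), a one-to-one ortholog map, and the ground truth used by tests:
each gene's class, its target tissue (tissue-specific genes only) and its
conservation level.

Generative model (log2 scale), for gene *i*, tissue *t*, species *s*::

    y[s,i,t] = b[i] + delta * 1{s=2} + c[i] * e[i,t]
               + (1 - c[i]) * e'[s,i,t] + eps[s,i,t]

where ``b[i]`` is a per-gene baseline drawn around the class mean,
``delta`` a species-wide intensity shift (microarray platforms for two
species are never on a common scale, so one species' intensity
distribution sits to the right of the other's), ``e`` the shared
tissue-effect profile, ``e'`` an independently drawn per-species profile
of the same shape, ``c[i]`` in [0, 1] the conservation weight that blends
them, and ``eps`` i.i.d. Gaussian measurement noise, independent between
species.  Returned intensities are ``2**y``: strictly positive, linear
scale, which the relative-expression transform requires.

Gene classes:

tissue_specific
    One target tissue receives a bump of ``tissue_effect_size`` log2
    units; under conservation < 1 each species blends in its own bump at
    an independently drawn tissue.
housekeeping
    Flat profile at a moderately high baseline; between-species
    differences are measurement noise only.
background
    Flat profile near the noise floor (the low-intensity mass that
    dominates genome-wide arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, OrthologPairSet
from .errors import ConfigError

__all__ = [
    "CLASS_LABELS",
    "DEFAULT_TISSUES",
    "SyntheticConfig",
    "GroundTruth",
    "generate_paired_expression",
    "generate_random_pairs",
]

CLASS_LABELS = ("tissue_specific", "housekeeping", "background")

#: Tissue panel used when ``n_tissues == 8`` (the classic eight-tissue
#: human/rat comparison panel); other sizes get generic labels.
DEFAULT_TISSUES = (
    "bone_marrow",
    "heart",
    "kidney",
    "pituitary",
    "skeletal_muscle",
    "small_intestine",
    "spleen",
    "thymus",
)

_DEFAULT_BASELINE = {
    "tissue_specific": 8.0,
    "housekeeping": 9.0,
    "background": 4.0,
}

_DEFAULT_CONSERVATION = {
    "tissue_specific": 0.9,
    "housekeeping": 0.0,
    "background": 0.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the paired-species generative model.

    All intensity-scale parameters are in log2 units.  ``conservation``
    may be a scalar applied to every gene, a mapping from class label to
    value, or a per-gene sequence of length ``n_genes``; ``None`` selects
    the per-class defaults (conserved tissue-specific genes, unconserved
    flat classes).
    """

    n_genes: int = 3152
    n_tissues: int = 8
    frac_tissue_specific: float = 0.25
    frac_housekeeping: float = 0.25
    frac_background: float = 0.50
    baseline_mean_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE)
    )
    baseline_sd: float = 1.0
    tissue_effect_size: float = 4.0
    conservation: float | Mapping[str, float] | Sequence[float] | None = None
    species_shift: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    species_names: tuple[str, str] = ("species1", "species2")

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be a positive integer")
        if self.n_tissues < 2:
            raise ConfigError("n_tissues must be at least 2")
        fracs = (
            self.frac_tissue_specific,
            self.frac_housekeeping,
            self.frac_background,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(
                f"class fractions must sum to 1 (got {sum(fracs):g})"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be non-negative")
        missing = [k for k in CLASS_LABELS if k not in self.baseline_mean_by_class]
        if missing:
            raise ConfigError(f"baseline_mean_by_class missing classes: {missing}")
        for c in np.atleast_1d(self._conservation_array(check_only=True)):
            if not (0.0 <= c <= 1.0):
                raise ConfigError("conservation values must lie in [0, 1]")

    def _conservation_array(self, check_only: bool = False) -> np.ndarray:
        """Raw conservation values for range checking (not yet per-gene)."""
        c = self.conservation
        if c is None:
            return np.array(list(_DEFAULT_CONSERVATION.values()))
        if isinstance(c, Mapping):
            missing = [k for k in CLASS_LABELS if k not in c]
            if missing:
                raise ConfigError(f"conservation mapping missing classes: {missing}")
            return np.array([float(c[k]) for k in CLASS_LABELS])
        if np.isscalar(c):
            return np.array([float(c)])
        arr = np.asarray(c, dtype=float)
        if not check_only and arr.shape != (self.n_genes,):
            raise ConfigError("per-gene conservation must have length n_genes")
        if arr.shape != (self.n_genes,):
            raise ConfigError("per-gene conservation must have length n_genes")
        return arr

    def conservation_for(self, class_labels: np.ndarray) -> np.ndarray:
        """Per-gene conservation vector resolved against ``class_labels``."""
        c = self.conservation
        if c is None:
            c = _DEFAULT_CONSERVATION
        if isinstance(c, Mapping):
            lut = {k: float(c[k]) for k in CLASS_LABELS}
            return np.array([lut[k] for k in class_labels])
        if np.isscalar(c):
            return np.full(len(class_labels), float(c))
        return np.asarray(c, dtype=float)


@dataclass(frozen=True)
class GroundTruth:
    """Per-gene truth record: class, target tissue, conservation.

    ``table`` is indexed by the species-1 gene id with columns
    ``class_label``, ``target_tissue`` (tissue label, NA unless the gene is
    tissue-specific) and ``conservation``.
    """

    table: pd.DataFrame

    def genes_of_class(self, label: str) -> pd.Index:
        if label not in CLASS_LABELS:
            raise ConfigError(f"unknown gene class {label!r}")
        return self.table.index[self.table["class_label"] == label]


def _tissue_labels(n_tissues: int) -> list[str]:
    if n_tissues == len(DEFAULT_TISSUES):
        return list(DEFAULT_TISSUES)
    return [f"tissue{j + 1:02d}" for j in range(n_tissues)]


def generate_paired_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologPairSet, GroundTruth]:
    """Simulate paired expression matrices for two species.

    Returns ``(matrix_species1, matrix_species2, ortholog_pairs, truth)``.
    Gene *i* of species 1 is the ortholog of gene *i* of species 2 (same
    identifier in both matrices).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_genes, config.n_tissues

    # Exact class counts by block assignment, then a seeded shuffle.
    n_ts = int(np.floor(n * config.frac_tissue_specific))
    n_hk = int(np.floor(n * config.frac_housekeeping))
    n_bg = n - n_ts - n_hk
    labels = np.array(
        ["tissue_specific"] * n_ts + ["housekeeping"] * n_hk + ["background"] * n_bg
    )
    labels = labels[rng.permutation(n)]
    ts_mask = labels == "tissue_specific"
    n_ts_eff = int(ts_mask.sum())

    base_mean = np.array([config.baseline_mean_by_class[k] for k in labels])
    b = base_mean + rng.normal(0.0, config.baseline_sd, size=n)

    target = np.full(n, -1)
    target[ts_mask] = rng.integers(0, T, size=n_ts_eff)

    cons = config.conservation_for(labels)

    e_shared = np.zeros((n, T))
    e_shared[np.flatnonzero(ts_mask), target[ts_mask]] = config.tissue_effect_size

    tissues = _tissue_labels(T)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    matrices = []
    for s in range(2):
        e_own = np.zeros((n, T))
        own_target = rng.integers(0, T, size=n_ts_eff)
        e_own[np.flatnonzero(ts_mask), own_target] = config.tissue_effect_size
        eps = rng.normal(0.0, config.noise_sd, size=(n, T)) if config.noise_sd > 0 else 0.0
        y = (
            b[:, None]
            + (config.species_shift if s == 1 else 0.0)
            + cons[:, None] * e_shared
            + (1.0 - cons[:, None]) * e_own
            + eps
        )
        frame = pd.DataFrame(np.exp2(y), index=gene_ids, columns=tissues)
        matrices.append(
            ExpressionMatrix(frame, species=config.species_names[s])
        )

    pairs = OrthologPairSet(gene_ids, gene_ids)
    truth = GroundTruth(
        pd.DataFrame(
            {
                "class_label": labels,
                "target_tissue": [
                    tissues[t] if t >= 0 else pd.NA for t in target
                ],
                "conservation": cons,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return matrices[0], matrices[1], pairs, truth


def generate_random_pairs(pairs: OrthologPairSet, seed: int) -> OrthologPairSet:
    """Re-pair species-1 genes with randomly permuted species-2 genes.

    The permutation is drawn uniformly and redrawn until it has no fixed
    point (a derangement), so no true ortholog pair survives into the
    random pairing -- with ~3000 genes a plain permutation would leave one
    true pair in the null on average, which would contaminate its lower
    tail.  Deterministic given ``seed``.
    """
    n = len(pairs)
    if n < 2:
        raise ConfigError("cannot derange fewer than 2 pairs")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not (perm == np.arange(n)).any():
            break
    b = np.asarray(pairs.species2_ids, dtype=object)[perm]
    return OrthologPairSet(pairs.species1_ids, b)
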