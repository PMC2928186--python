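"""Cross-species tissue clustering and homologous-pair scoring.

A good divergence measure should cluster homologous tissues across
species -- human kidney next to rat kidney -- rather than grouping
tissues within a species.  This module builds the 2T x 2T dissimilarity
matrix over the pooled tissue samples of both species (columns over the
aligned ortholog genes, after the measure-appropriate per-gene
transform), runs average-link (UPGMA-style) agglomeration on it, and
scores the resulting tree by counting tissues whose two species samples
form a cherry (a two-leaf clade).  The cherry criterion is strict: a
tissue gets credit only when its two samples are each other's nearest
neighbors in the tree, so a topology like
``(((thymus@rat, spleen@rat), thymus@human), spleen@human)`` scores zero
for both tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, OrthologPairSet
from .distances import (
    binary_correlation_distance,
    correlation_distance,
    euclidean_distance,
    ga_distance,
)
from .errors import ValidationError
from .transforms import to_binary, to_relative

__all__ = [
    "SampleDistanceMatrix",
    "LinkageTree",
    "TreeNode",
    "sample_distance_matrix",
    "average_link_cluster",
    "homologous_pairing_score",
]

SAMPLE_SEP = "@"


@dataclass(frozen=True)
class SampleDistanceMatrix:
    """Symmetric dissimilarity matrix over labelled samples.

    Labels take the form ``tissue@species``.  The diagonal is zero and no
    entry may be undefined (``nan``): an undefined column pair indicates a
    degenerate sample and is raised as an error upstream.
    """

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValidationError("distance matrix shape does not match labels")
        if np.isnan(v).any():
            raise ValidationError("distance matrix contains undefined entries")
        if (v < 0).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)


_SCALAR = {
    "euclidean": euclidean_distance,
    "correlation": correlation_distance,
    "binary_correlation": binary_correlation_distance,
}


def sample_distance_matrix(
    matA: ExpressionMatrix,
    matB: ExpressionMatrix,
    pairs: OrthologPairSet,
    measure: str,
    params: dict | None = None,
) -> SampleDistanceMatrix:
    """Dissimilarities between all 2T tissue samples of the two species.

    Rows are first restricted to the ortholog pairs and aligned (row *k*
    of each species is the *k*-th pair); the per-gene transform (relative
    for ``euclidean``/``correlation``, binary for the binary measures) is
    applied across tissues *before* columns are extracted, because both
    transforms are defined gene-wise.  Entry (s, s') is then the scalar
    distance between the two samples' column vectors over the aligned
    genes.  An undefined column pair (constant or all-zero sample) raises
    an error naming the samples involved.
    """
    params = dict(params or {})
    if measure in ("euclidean", "correlation"):
        ta, tb = to_relative(matA), to_relative(matB)
    elif measure in ("binary_correlation", "ga"):
        ta, tb = to_binary(matA), to_binary(matB)
    else:
        raise ValidationError(f"unknown measure {measure!r}")

    idx_a = ta.gene_ids.get_indexer(list(pairs.species1_ids))
    idx_b = tb.gene_ids.get_indexer(list(pairs.species2_ids))
    for idx, ids, side in ((idx_a, pairs.species1_ids, "species-1"),
                           (idx_b, pairs.species2_ids, "species-2")):
        if (idx < 0).any():
            missing = [g for g, i in zip(ids, idx) if i < 0][0]
            raise ValidationError(f"gene {missing!r} not found in {side} matrix")

    cols = []
    labels = []
    for mat, trans, idx in ((matA, ta, idx_a), (matB, tb, idx_b)):
        aligned = trans.values[idx]
        for j, tissue in enumerate(mat.tissue_labels):
            cols.append(aligned[:, j])
            labels.append(f"{tissue}{SAMPLE_SEP}{mat.species}")

    if measure == "ga":
        if "lam" not in params:
            raise ValidationError("measure 'ga' requires a 'lam' parameter")
        lam = float(params["lam"])
        scalar = lambda u, v: ga_distance(u, v, lam)  # noqa: E731
    else:
        scalar = _SCALAR[measure]

    k = len(cols)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            val = scalar(cols[i], cols[j])
            if np.isnan(val):
                raise ValidationError(
                    f"distance undefined between samples {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = val
    return SampleDistanceMatrix(labels=tuple(labels), values=d)


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted clustering tree; ``height`` is the merge level."""

    height: float
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class LinkageTree:
    """Rooted binary tree from average-link agglomeration.

    ``merges`` records the agglomeration sequence as
    ``(members_i, members_j, height)`` tuples of frozensets of leaf
    labels, in merge order; heights are non-decreasing (an average-link
    guarantee).
    """

    root: TreeNode
    merges: tuple

    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""

        def render(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{length:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.10g}"

        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def average_link_cluster(D: SampleDistanceMatrix) -> LinkageTree:
    """UPGMA-style agglomeration on the given dissimilarities.

    Repeatedly merges the closest pair of clusters; the distance between
    clusters is the unweighted arithmetic mean of all cross-pair
    dissimilarities (maintained by the size-weighted Lance-Williams
    update).  Ties are broken deterministically by the lexicographically
    smallest (i, j) position pair in the current cluster ordering, where
    merged clusters are appended at the end of the ordering.
    """
    k = D.n
    if k < 2:
        raise ValidationError("need at least two samples to cluster")
    nodes = [TreeNode(height=0.0, label=lbl) for lbl in D.labels]
    sizes = [1] * k
    members = [frozenset([lbl]) for lbl in D.labels]
    dist = [list(row) for row in D.values]
    active = list(range(k))
    merges = []

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                d = dist[active[ai]][active[aj]]
                if best is None or d < best[0]:
                    best = (d, ai, aj)
        d, ai, aj = best
        i, j = active[ai], active[aj]
        merged = TreeNode(height=d, children=(nodes[i], nodes[j]))
        merges.append((members[i], members[j], d))

        # Lance-Williams average-link update against every other cluster.
        new_row = []
        si, sj = sizes[i], sizes[j]
        for other in active:
            if other in (i, j):
                continue
            new_row.append(
                (si * dist[i][other] + sj * dist[j][other]) / (si + sj)
            )
        nodes.append(merged)
        sizes.append(si + sj)
        members.append(members[i] | members[j])
        new_index = len(nodes) - 1
        for row in dist:
            row.append(0.0)
        dist.append([0.0] * (new_index + 1))
        remaining = [a for a in active if a not in (i, j)]
        for other, nd in zip(remaining, new_row):
            dist[new_index][other] = dist[other][new_index] = nd
        active = remaining + [new_index]

    return LinkageTree(root=nodes[active[0]], merges=tuple(merges))


def homologous_pairing_score(tree: LinkageTree, sep: str = SAMPLE_SEP) -> int:
    """Number of tissues whose two species samples form a cherry.

    Leaf labels must parse as ``tissue@species`` with exactly two species
    present.  Invariant under child-order rotations.  Returns an integer
    in ``[0, T]`` where ``T`` is the number of tissues.
    """
    leaves = tree.leaf_labels()
    parsed = []
    for lbl in leaves:
        if sep not in lbl:
            raise ValidationError(f"sample label {lbl!r} is not of the form tissue{sep}species")
        tissue, species = lbl.rsplit(sep, 1)
        parsed.append((tissue, species))
    species = {s for _, s in parsed}
    if len(species) != 2:
        raise ValidationError(f"expected exactly two species in leaf labels, got {sorted(species)}")

    score = 0
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        kids = node.children
        if len(kids) == 2 and all(c.is_leaf for c in kids):
            (t1, s1), (t2, s2) = (
                kids[0].label.rsplit(sep, 1),
                kids[1].label.rsplit(sep, 1),
            )
            if t1 == t2 and s1 != s2:
                score += 1
        stack.extend(kids)
    return score
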