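import itertools
import math

import numpy as np
import pytest

from exprdiv import (
    LinkageTree,
    OrthologPairSet,
    SampleDistanceMatrix,
    ValidationError,
    average_link_cluster,
    homologous_pairing_score,
    sample_distance_matrix,
)
from exprdiv.cluster import TreeNode
from .conftest import make_expression


def naive_average_link(labels, values):
    """Independent agglomerator: recomputes every cross-pair mean each step."""
    clusters = [frozenset([lbl]) for lbl in labels]
    index = {lbl: i for i, lbl in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            pairs = [
                values[index[x]][index[y]]
                for x in clusters[a]
                for y in clusters[b]
            ]
            d = sum(pairs) / len(pairs)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def dm(labels, values):
    return SampleDistanceMatrix(labels=tuple(labels), values=np.asarray(values, float))


class TestAverageLink:
    def test_three_sample_hand_agglomeration(self):
        D = dm("abc", [[0, 1, 10], [1, 0, 10], [10, 10, 0]])
        tree = average_link_cluster(D)
        (m1a, m1b, h1), (m2a, m2b, h2) = tree.merges
        assert {m1a, m1b} == {frozenset("a"), frozenset("b")}
        assert h1 == 1 and h2 == 10
        assert {m2a, m2b} == {frozenset("ab"), frozenset("c")}

    def test_all_equal_distances_single_height(self):
        v = 2.5
        D = dm("abcd", v * (1 - np.eye(4)))
        tree = average_link_cluster(D)
        assert tree.merges[0][2] == v
        assert tree.root.height == v

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            m = rng.uniform(0.1, 10, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"s{i}" for i in range(n)]
            tree = average_link_cluster(dm(labels, m))
            oracle = naive_average_link(labels, m)
            assert len(tree.merges) == len(oracle)
            for (a, b, h), (oa, ob, oh) in zip(tree.merges, oracle):
                assert {a, b} == {oa, ob}
                assert h == pytest.approx(oh, rel=1e-10)

    def test_merge_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(6)
        m = rng.uniform(1, 5, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = average_link_cluster(dm([f"s{i}" for i in range(10)], m))
        ours = sorted(h for _, _, h in tree.merges)
        scipy_heights = sorted(linkage(squareform(m), method="average")[:, 2])
        np.testing.assert_allclose(ours, scipy_heights, rtol=1e-10)

    def test_heights_non_decreasing_to_root(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0.5, 3, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = average_link_cluster(dm([f"s{i}" for i in range(8)], m))

        def check(node):
            for child in node.children:
                assert child.height <= node.height + 1e-12
                check(child)

        check(tree.root)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            dm("ab", [[0, 1], [2, 0]])  # asymmetric
        with pytest.raises(ValidationError):
            dm("ab", [[0, -1], [-1, 0]])  # negative
        with pytest.raises(ValidationError):
            dm("ab", [[0.5, 1], [1, 0]])  # nonzero diagonal


def cherry(t, h=0.1):
    return TreeNode(
        height=h,
        children=(
            TreeNode(0.0, label=f"{t}@human"),
            TreeNode(0.0, label=f"{t}@rat"),
        ),
    )


class TestPairingScore:
    def test_perfect_recovery_scores_t(self):
        kids = [cherry(t) for t in ("heart", "kidney", "spleen", "thymus")]
        root = TreeNode(height=1.0, children=(
            TreeNode(0.5, children=(kids[0], kids[1])),
            TreeNode(0.5, children=(kids[2], kids[3])),
        ))
        tree = LinkageTree(root=root, merges=())
        assert homologous_pairing_score(tree) == 4

    def test_caterpillar_alternating_species_scores_zero(self):
        leaves = [
            TreeNode(0.0, label=f"{t}@{s}")
            for t, s in [("heart", "human"), ("kidney", "rat"),
                         ("heart", "rat"), ("kidney", "human")]
        ]
        node = leaves[0]
        for i, leaf in enumerate(leaves[1:], 1):
            node = TreeNode(height=float(i), children=(node, leaf))
        assert homologous_pairing_score(LinkageTree(root=node, merges=())) == 0

    def test_nested_misplacement_scores_zero_for_both_tissues(self):
        # (((thymus@rat, spleen@rat), thymus@human), spleen@human)
        inner = TreeNode(0.1, children=(
            TreeNode(0.0, label="thymus@rat"),
            TreeNode(0.0, label="spleen@rat"),
        ))
        mid = TreeNode(0.5, children=(inner, TreeNode(0.0, label="thymus@human")))
        root = TreeNode(1.0, children=(mid, TreeNode(0.0, label="spleen@human")))
        assert homologous_pairing_score(LinkageTree(root=root, merges=())) == 0

    def test_invariant_to_child_rotation(self):
        a, b = cherry("heart"), cherry("kidney")
        t1 = LinkageTree(root=TreeNode(1.0, children=(a, b)), merges=())
        t2 = LinkageTree(root=TreeNode(1.0, children=(b, a)), merges=())
        rot = TreeNode(a.height, children=(a.children[1], a.children[0]))
        t3 = LinkageTree(root=TreeNode(1.0, children=(rot, b)), merges=())
        assert (
            homologous_pairing_score(t1)
            == homologous_pairing_score(t2)
            == homologous_pairing_score(t3)
            == 2
        )

    def test_malformed_labels_rejected(self):
        bad = LinkageTree(
            root=TreeNode(1.0, children=(
                TreeNode(0.0, label="heart"),
                TreeNode(0.0, label="kidney@rat"),
            )),
            merges=(),
        )
        with pytest.raises(ValidationError):
            homologous_pairing_score(bad)


class TestSampleDistanceMatrix:
    @pytest.fixture
    def small_pair(self):
        rng = np.random.default_rng(9)
        a = make_expression(rng.lognormal(3, 1, (12, 4)), species="human",
                            tissues=["heart", "kidney", "spleen", "thymus"])
        b = make_expression(rng.lognormal(3, 1, (12, 4)), species="rat",
                            tissues=["heart", "kidney", "spleen", "thymus"])
        return a, b, OrthologPairSet(a.gene_ids, b.gene_ids)

    @pytest.mark.parametrize("measure,params", [
        ("euclidean", {}),
        ("correlation", {}),
        ("binary_correlation", {}),
        ("ga", {"lam": math.inf}),
    ])
    def test_copy_of_self_has_zero_cross_distance(self, small_pair, measure, params):
        a, _, pairs = small_pair
        b = make_expression(a.values, species="rat", tissues=list(a.tissue_labels))
        sdm = sample_distance_matrix(a, b, pairs, measure, params)
        for t in a.tissue_labels:
            i = sdm.labels.index(f"{t}@human")
            j = sdm.labels.index(f"{t}@rat")
            assert sdm.values[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_gene_order_permutation_invariance(self, small_pair):
        a, b, pairs = small_pair
        perm = np.random.default_rng(11).permutation(a.n_genes)
        ap = make_expression(a.values[perm], species="human",
                             genes=[a.gene_ids[i] for i in perm],
                             tissues=list(a.tissue_labels))
        bp = make_expression(b.values[perm], species="rat",
                             genes=[b.gene_ids[i] for i in perm],
                             tissues=list(b.tissue_labels))
        s1 = sample_distance_matrix(a, b, pairs, "correlation")
        s2 = sample_distance_matrix(ap, bp, pairs, "correlation")
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)

    def test_entries_match_explicit_column_extraction(self, small_pair):
        from exprdiv import correlation_distance, to_relative

        a, b, pairs = small_pair
        sdm = sample_distance_matrix(a, b, pairs, "correlation")
        rel_a, rel_b = to_relative(a), to_relative(b)
        cols = {f"{t}@human": rel_a.data[t].to_numpy() for t in a.tissue_labels}
        cols.update({f"{t}@rat": rel_b.data[t].to_numpy() for t in b.tissue_labels})
        for i, li in enumerate(sdm.labels):
            for j, lj in enumerate(sdm.labels):
                if i < j:
                    assert sdm.values[i, j] == pytest.approx(
                        correlation_distance(cols[li], cols[lj]), abs=1e-12
                    )

    def test_degenerate_sample_column_raises_naming_sample(self):
        # tissue00 dominates every gene, so every binary column for the
        # other tissue is all-zero -> GA undefined for that sample pair
        a = make_expression([[100, 1], [90, 2], [80, 1]], species="human")
        b = make_expression([[100, 1], [90, 2], [80, 1]], species="rat")
        pairs = OrthologPairSet(a.gene_ids, b.gene_ids)
        with pytest.raises(ValidationError, match="tissue01"):
            sample_distance_matrix(a, b, pairs, "ga", {"lam": 1.0})
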