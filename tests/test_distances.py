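import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from exprdiv import (
    ValidationError,
    correlation_distance,
    euclidean_distance,
    ga_distance,
    ga_power_mean,
    pairwise_distances,
    to_binary,
    to_relative,
)
from .conftest import make_expression

LAMBDAS = (-math.inf, -10.0, -1.0, 0.0, 1.0, 10.0, math.inf)


def all_binary_vectors(length=8):
    return np.array(
        [v for v in itertools.product((0, 1), repeat=length) if any(v)], dtype=float
    )


class TestEuclidean:
    def test_worked_values(self):
        assert euclidean_distance([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert euclidean_distance([1, 0], [0, 1]) == pytest.approx(math.sqrt(2))
        assert euclidean_distance([0.25, 0.75], [0.5, 0.5]) == pytest.approx(
            math.sqrt(0.125)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        u = np.array([1.0, 2.0, 5.0, 3.0])
        assert correlation_distance(u, 3 * u + 2) == pytest.approx(0.0, abs=1e-12)
        assert correlation_distance(u, -u + 10) == pytest.approx(2.0, abs=1e-12)

    def test_worked_pearson(self):
        assert correlation_distance([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.2)

    def test_constant_vector_undefined(self):
        assert math.isnan(correlation_distance([1, 1, 1], [1, 2, 3]))
        assert math.isnan(correlation_distance([1, 2, 3], [5, 5, 5]))

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=8),
        st.floats(0.1, 50),
        st.floats(-20, 20),
        st.floats(0.1, 50),
        st.floats(-20, 20),
    )
    def test_affine_invariance(self, u, a1, b1, a2, b2):
        u = np.asarray(u)
        v = np.sin(u) + np.arange(len(u))  # deterministic non-constant partner
        d0 = correlation_distance(u, v)
        d1 = correlation_distance(a1 * u + b1, a2 * v + b2)
        if not math.isnan(d0):
            assert d1 == pytest.approx(d0, abs=1e-6)


class TestGA:
    def test_identical_vectors_zero_any_lambda(self):
        u = np.array([1, 0, 1, 1, 0, 0, 0, 0])
        for lam in LAMBDAS:
            assert ga_distance(u, u, lam) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_distance_one(self):
        u = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        v = np.array([0, 0, 1, 1, 1, 0, 0, 0])
        for lam in LAMBDAS:
            assert ga_distance(u, v, lam) == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_simpson_dice_max(self):
        u = np.array([1, 1, 1, 0, 0, 0, 0, 0])  # m = 3
        v = np.array([1, 1, 0, 0, 0, 0, 0, 0])  # n = 2, X = 2
        assert ga_distance(u, v, -math.inf) == pytest.approx(0.0)
        assert ga_distance(u, v, 1.0) == pytest.approx(0.2)
        assert ga_distance(u, v, math.inf) == pytest.approx(1 / 3)

    def test_empty_vector_undefined(self):
        assert math.isnan(ga_distance([0, 0, 0], [1, 0, 1], 1.0))

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            ga_distance([0.5, 1], [1, 0], 1.0)

    def test_symmetry_over_enumeration_sample(self):
        rng = np.random.default_rng(4)
        vecs = all_binary_vectors(8)
        idx = rng.integers(0, len(vecs), size=(200, 2))
        for i, j in idx:
            for lam in (-math.inf, -2.0, 0.0, 1.0, 3.0, math.inf):
                assert ga_distance(vecs[i], vecs[j], lam) == ga_distance(
                    vecs[j], vecs[i], lam
                )

    def test_large_lambda_converges_to_limits(self):
        """ga(lam) -> ga(+-inf) at the power-mean rate ln2/|lam|.

        The power mean of two values approaches max (resp. min) like
        ``2**(-1/lam)``, i.e. the distance error is bounded by
        ``ln(2)/|lam|``; verify the bound on every length-8 pair and that
        the error shrinks accordingly as |lam| grows.
        """
        vecs = all_binary_vectors(8)
        m = vecs.sum(axis=1)
        x = vecs @ vecs.T
        mm, nn = m[:, None], m[None, :]
        for sign in (1.0, -1.0):
            limit = sign * math.inf
            d_lim = 1 - x / ga_power_mean(mm, nn, limit)
            errs = []
            for mag in (50.0, 1000.0, 1e6):
                d_big = 1 - x / ga_power_mean(mm, nn, sign * mag)
                err = np.nanmax(np.abs(d_big - d_lim))
                assert err <= math.log(2) / mag * 1.01
                errs.append(err)
            assert errs[0] >= errs[1] >= errs[2]
            assert errs[2] < 1e-6

    def test_power_mean_no_overflow_at_extreme_exponents(self):
        b = ga_power_mean(np.array([1.0]), np.array([8.0]), 1000.0)
        assert np.isfinite(b).all() and b[0] == pytest.approx(8.0, rel=1e-3)
        b = ga_power_mean(np.array([1.0]), np.array([8.0]), -1000.0)
        assert np.isfinite(b).all() and b[0] == pytest.approx(1.0, rel=1e-3)


class TestPairwise:
    def test_matches_scalar_loop_on_fixture(self, five_gene_pair):
        a, b, pairs = five_gene_pair
        rel_a, rel_b = to_relative(a), to_relative(b)
        bin_a, bin_b = to_binary(a), to_binary(b)
        cases = [
            ("euclidean", {}, rel_a, rel_b, euclidean_distance),
            ("correlation", {}, rel_a, rel_b, correlation_distance),
            ("binary_correlation", {}, bin_a, bin_b, correlation_distance),
            ("ga", {"lam": 2.0}, bin_a, bin_b, lambda u, v: ga_distance(u, v, 2.0)),
            ("ga", {"lam": math.inf}, bin_a, bin_b,
             lambda u, v: ga_distance(u, v, math.inf)),
        ]
        for measure, params, ta, tb, scalar in cases:
            out = pairwise_distances(ta, tb, pairs, measure, params)
            expected = [
                scalar(ta.values[i], tb.values[i]) for i in range(len(pairs))
            ]
            expected = [e for e in expected if not math.isnan(e)]
            np.testing.assert_allclose(out.values, expected, atol=1e-12)
            assert out.n_excluded + out.n_defined == len(pairs)

    def test_identical_matrices_identity_pairs_all_zero(self, five_gene_pair):
        a, _, _ = five_gene_pair
        from exprdiv import OrthologPairSet

        pairs = OrthologPairSet(a.gene_ids, a.gene_ids)
        rel = to_relative(a)
        binm = to_binary(a)
        for measure, params, mat in [
            ("euclidean", {}, rel),
            ("correlation", {}, rel),
            ("binary_correlation", {}, binm),
            ("ga", {"lam": 0.0}, binm),
        ]:
            out = pairwise_distances(mat, mat, pairs, measure, params)
            np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_undefined_pairs_excluded_and_counted(self):
        # gene g001 is uniform: zero variance after the relative transform
        a = make_expression([[1, 2, 3, 4], [5, 5, 5, 5], [9, 1, 1, 1]])
        b = make_expression([[4, 3, 2, 1], [1, 2, 1, 2], [2, 2, 5, 9]], species="species2")
        from exprdiv import OrthologPairSet

        pairs = OrthologPairSet(a.gene_ids, b.gene_ids)
        out = pairwise_distances(to_relative(a), to_relative(b), pairs, "correlation")
        assert out.n_defined == 2
        assert out.n_excluded == 1
        assert out.excluded_ids[0][0] == "g001"
        out_e = pairwise_distances(to_relative(a), to_relative(b), pairs, "euclidean")
        assert out_e.n_excluded == 0

    def test_order_preserved_and_shape_contract(self, five_gene_pair):
        a, b, pairs = five_gene_pair
        out = pairwise_distances(to_relative(a), to_relative(b), pairs, "euclidean")
        assert out.pair_ids == tuple(zip(pairs.species1_ids, pairs.species2_ids))
        assert len(out.values) == len(pairs)

    def test_unknown_gene_and_bad_inputs_rejected(self, five_gene_pair):
        a, b, pairs = five_gene_pair
        from exprdiv import OrthologPairSet

        bad_pairs = OrthologPairSet(["nope"], [b.gene_ids[0]])
        with pytest.raises(ValidationError, match="nope"):
            pairwise_distances(to_relative(a), to_relative(b), bad_pairs, "euclidean")
        with pytest.raises(ValidationError):  # wrong transform for the measure
            pairwise_distances(to_relative(a), to_relative(b), pairs, "ga", {"lam": 1})
        with pytest.raises(ValidationError):  # missing lambda
            pairwise_distances(to_binary(a), to_binary(b), pairs, "ga")
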