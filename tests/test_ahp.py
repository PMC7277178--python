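"""AHP engine: eigenvector weights, consistency, aggregation, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcda4hta import (
    PairwiseComparisonMatrix,
    WeightVector,
    aggregate_judgments,
    consistency_ratio,
    principal_weights,
    synthesize_global_weights,
)
from mcda4hta.ahp import RANDOM_INDEX, snap_to_saaty
from mcda4hta.errors import MatrixError
from mcda4hta.hierarchy import ROOT_ID

# frozen from an independent numpy.linalg.eig decomposition of
# [[1, 2, 5], [1/2, 1, 3], [1/5, 1/3, 1]]
ORACLE_MATRIX = np.array([[1.0, 2.0, 5.0], [0.5, 1.0, 3.0], [0.2, 1 / 3, 1.0]])
ORACLE_WEIGHTS = np.array([0.58155207, 0.30899564, 0.10945229])
ORACLE_LAMBDA = 3.00369459806364
ORACLE_CR = 0.0031849983307239735


def consistent_matrix(w: np.ndarray, mid: str = "m") -> PairwiseComparisonMatrix:
    return PairwiseComparisonMatrix(mid, np.outer(w, 1.0 / w))


class TestMatrixValidation:
    def test_reciprocity_enforced(self):
        bad = np.array([[1.0, 2.0], [0.4, 1.0]])
        with pytest.raises(MatrixError, match="reciprocity"):
            PairwiseComparisonMatrix("m", bad)

    def test_diagonal_must_be_one(self):
        with pytest.raises(MatrixError):
            PairwiseComparisonMatrix("m", np.array([[2.0, 1.0], [1.0, 1.0]]))

    def test_from_upper_fills_reciprocals(self):
        m = PairwiseComparisonMatrix.from_upper("m", 3, {(0, 1): 3.0, (0, 2): 5.0, (1, 2): 2.0})
        assert m.values[1, 0] == pytest.approx(1 / 3)
        assert m.values[2, 0] == pytest.approx(1 / 5)


class TestPrincipalWeights:
    def test_all_ones_matrix(self):
        m = PairwiseComparisonMatrix("m", np.ones((3, 3)))
        w, lam = principal_weights(m)
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
        assert lam == pytest.approx(3.0, abs=1e-9)

    def test_consistent_matrix_recovers_generator(self):
        truth = np.array([0.6, 0.3, 0.1])
        w, lam = principal_weights(consistent_matrix(truth))
        np.testing.assert_allclose(w, truth, atol=1e-9)
        assert lam == pytest.approx(3.0, abs=1e-9)

    def test_against_eigendecomposition_oracle(self):
        m = PairwiseComparisonMatrix("m", ORACLE_MATRIX)
        w, lam = principal_weights(m)
        np.testing.assert_allclose(w, ORACLE_WEIGHTS, atol=1e-7)
        assert lam == pytest.approx(ORACLE_LAMBDA, abs=1e-9)

    def test_geometric_mean_route_agrees_for_consistent(self):
        truth = np.array([0.5, 0.25, 0.15, 0.10])
        w, _ = principal_weights(consistent_matrix(truth), method="geometric_mean")
        np.testing.assert_allclose(w, truth, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        m = PairwiseComparisonMatrix("m", ORACLE_MATRIX)
        perm = rng.permutation(3)
        mp = PairwiseComparisonMatrix("m", ORACLE_MATRIX[np.ix_(perm, perm)])
        w, _ = principal_weights(m)
        wp, _ = principal_weights(mp)
        np.testing.assert_allclose(wp, w[perm], atol=1e-9)


class TestConsistencyRatio:
    def test_consistent_matrix_is_zero(self):
        assert consistency_ratio(consistent_matrix(np.array([0.7, 0.2, 0.1]))) == \
            pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_always_zero(self):
        m = PairwiseComparisonMatrix.from_upper("m", 2, {(0, 1): 7.0})
        assert consistency_ratio(m) == 0.0

    def test_oracle_value(self):
        assert consistency_ratio(PairwiseComparisonMatrix("m", ORACLE_MATRIX)) == \
            pytest.approx(ORACLE_CR, abs=1e-9)

    def test_order_above_table_rejected(self):
        w = np.random.default_rng(0).dirichlet(np.ones(11))
        with pytest.raises(MatrixError, match="random index"):
            consistency_ratio(consistent_matrix(w))

    def test_random_index_table_orders(self):
        assert set(RANDOM_INDEX) == set(range(1, 11))


class TestAggregation:
    def test_single_matrix_identity(self):
        m = PairwiseComparisonMatrix("m", ORACLE_MATRIX)
        np.testing.assert_allclose(aggregate_judgments([m]).values, m.values)

    def test_opposite_judgments_cancel(self):
        a = PairwiseComparisonMatrix.from_upper("m", 2, {(0, 1): 3.0})
        b = PairwiseComparisonMatrix.from_upper("m", 2, {(0, 1): 1 / 3})
        assert aggregate_judgments([a, b]).values[0, 1] == pytest.approx(1.0)

    def test_idempotence_over_twelve_copies(self):
        m = PairwiseComparisonMatrix("m", ORACLE_MATRIX)
        agg = aggregate_judgments([m] * 12)
        np.testing.assert_allclose(agg.values, m.values, atol=1e-12)

    def test_mismatched_ids_rejected(self):
        a = PairwiseComparisonMatrix.from_upper("m1", 2, {(0, 1): 2.0})
        b = PairwiseComparisonMatrix.from_upper("m2", 2, {(0, 1): 2.0})
        with pytest.raises(MatrixError):
            aggregate_judgments([a, b])

    @given(st.lists(st.floats(0.2, 5.0), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_reciprocity_preserved_exactly(self, ratios):
        mats = [PairwiseComparisonMatrix.from_upper("m", 2, {(0, 1): r}) for r in ratios]
        agg = aggregate_judgments(mats).values
        # reciprocal is assigned algebraically; product is 1 to one ulp
        assert agg[0, 1] * agg[1, 0] == pytest.approx(1.0, abs=1e-15)


class TestGlobalSynthesis:
    def test_forced_arithmetic_example(self, two_level_hierarchy):
        locals_ = {
            ROOT_ID: WeightVector({"A": 0.5, "B": 0.5}),
            "A": WeightVector({"A1": 0.4, "A2": 0.6}),
        }
        gw = synthesize_global_weights(two_level_hierarchy, locals_)
        assert gw.weights == pytest.approx({"A1": 0.2, "A2": 0.3, "B": 0.5})

    def test_chain_child_inherits_weight_one(self, chain_hierarchy):
        gw = synthesize_global_weights(chain_hierarchy, {})
        assert gw.weights == {"A1": 1.0}

    def test_missing_local_vector_rejected(self, two_level_hierarchy):
        with pytest.raises(MatrixError, match="missing local"):
            synthesize_global_weights(
                two_level_hierarchy, {ROOT_ID: WeightVector({"A": 0.5, "B": 0.5})}
            )

    def test_leaf_weights_sum_to_one_on_random_trees(self):
        from mcda4hta import SyntheticSpec, gen_hierarchy, gen_true_weights

        for seed in range(5):
            spec = SyntheticSpec(seed=seed, shape=(4, 3, 2))
            h = gen_hierarchy(spec)
            gw = synthesize_global_weights(h, gen_true_weights(spec, h))
            assert sum(gw.weights.values()) == pytest.approx(1.0, abs=1e-9)
            # brute-force path-product oracle
            for leaf in h.leaves():
                w = 1.0
                node = leaf.id
                while node != ROOT_ID:
                    parent = h.nodes[node].parent_id
                    sibs = h.children(parent)
                    if len(sibs) >= 2:
                        w *= gen_true_weights(spec, h)[parent].weights[node]
                    node = parent
                assert gw.weights[leaf.id] == pytest.approx(w, rel=1e-9)


def test_saaty_snapping_hits_scale_points():
    assert snap_to_saaty(2.9) == 3.0
    assert snap_to_saaty(0.34) == pytest.approx(1 / 3)
    assert snap_to_saaty(1.05) == 1.0
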