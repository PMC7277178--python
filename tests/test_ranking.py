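"""Ranking engines: hand-computed examples, oracles, and shared invariants."""

import numpy as np
import pandas as pd
import pytest

from mcda4hta import (
    FuzzyDecisionMatrix,
    fuzzify_table,
    load_table,
    normalize_matrix,
    rank_fuzzy_topsis,
    rank_fuzzy_vikor,
    rank_goal_programming,
)
from mcda4hta.errors import MCDAError

from conftest import random_decision_matrix


def crisp_matrix(values, weights, directions=None, normalized=True):
    """Degenerate-TFN matrix from a 2-D array of crisp scores."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return FuzzyDecisionMatrix(
        alternatives=tuple(f"A{i}" for i in range(n)),
        columns=tuple(f"c{j}" for j in range(m)),
        tfns=np.repeat(values[:, :, None], 3, axis=2),
        weights=np.asarray(weights, dtype=float),
        directions=tuple(directions or ["benefit"] * m),
        normalized=normalized,
    )


class TestTopsis:
    def test_single_criterion_hand_example(self):
        # crisp 10 and 5, weight 1: normalized 1 and 0.5 -> indices 0 and 0.5
        f = crisp_matrix([[1.0], [0.5]], [1.0])
        r = rank_fuzzy_topsis(f)
        assert r.indices["A0"] == pytest.approx(0.0)
        assert r.indices["A1"] == pytest.approx(0.5)
        assert r.ranks == {"A0": 1, "A1": 2}

    def test_identical_alternatives_get_equal_indices(self):
        f = crisp_matrix([[0.7, 0.4], [0.7, 0.4]], [0.5, 0.5])
        r = rank_fuzzy_topsis(f)
        assert r.indices["A0"] == pytest.approx(r.indices["A1"])

    def test_complement_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            f = random_decision_matrix(rng, n_alt=3, n_col=4)
            r = rank_fuzzy_topsis(f)
            for a in f.alternatives:
                dp = r.intermediates["d_plus"][a]
                dm = r.intermediates["d_minus"][a]
                assert dm / (dp + dm) == pytest.approx(1.0 - r.indices[a], abs=1e-12)

    def test_brute_force_recomputation_oracle(self):
        """Index must equal an independent per-cell loop over the formula."""
        import math

        rng = np.random.default_rng(7)
        for _ in range(100):
            f = random_decision_matrix(rng, n_alt=3, n_col=4)
            r = rank_fuzzy_topsis(f)
            for i, a in enumerate(f.alternatives):
                dp = dm = 0.0
                for j, w in enumerate(f.weights):
                    cell = f.tfns[i, j] * w
                    dp += math.sqrt(sum((cell[k] - w) ** 2 for k in range(3)) / 3)
                    dm += math.sqrt(sum(cell[k] ** 2 for k in range(3)) / 3)
                assert r.indices[a] == pytest.approx(dp / (dp + dm), abs=1e-12)

    def test_requires_normalized_matrix(self):
        f = crisp_matrix([[10.0], [5.0]], [1.0], normalized=False)
        with pytest.raises(MCDAError, match="normalized"):
            rank_fuzzy_topsis(f)

    def test_index_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            r = rank_fuzzy_topsis(random_decision_matrix(rng, 4, 5))
            assert all(0.0 <= v <= 1.0 for v in r.indices.values())


class TestVikor:
    def test_dominator_gets_zero_other_one(self):
        f = crisp_matrix([[1.0, 1.0], [0.5, 0.25]], [0.5, 0.5])
        r = rank_fuzzy_vikor(f, 0.5)
        assert r.indices["A0"] == pytest.approx(0.0)
        assert r.indices["A1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_alt,n_col", [(3, 3), (4, 5)])
    def test_v_limits_reduce_to_s_and_r_orderings(self, n_alt, n_col):
        rng = np.random.default_rng(17)
        for _ in range(100):
            f = random_decision_matrix(rng, n_alt, n_col)
            r1 = rank_fuzzy_vikor(f, 1.0)
            r0 = rank_fuzzy_vikor(f, 0.0)
            S, R = r1.intermediates["S"], r0.intermediates["R"]
            s_order = sorted(f.alternatives, key=lambda a: S[a])
            r_order = sorted(f.alternatives, key=lambda a: R[a])
            q1_order = sorted(f.alternatives, key=lambda a: r1.indices[a])
            q0_order = sorted(f.alternatives, key=lambda a: r0.indices[a])
            assert [S[a] for a in q1_order] == pytest.approx([S[a] for a in s_order])
            assert [R[a] for a in q0_order] == pytest.approx([R[a] for a in r_order])

    def test_identical_alternatives_all_zero(self):
        f = crisp_matrix([[0.5, 0.5], [0.5, 0.5]], [0.6, 0.4])
        r = rank_fuzzy_vikor(f)
        assert all(v == 0.0 for v in r.indices.values())

    def test_q_in_unit_interval_with_extremes_attained(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            f = random_decision_matrix(rng, 3, 4)
            r = rank_fuzzy_vikor(f)
            vals = list(r.indices.values())
            assert min(vals) >= -1e-12 and max(vals) <= 1 + 1e-12

    def test_invalid_v_rejected(self):
        f = crisp_matrix([[1.0], [0.5]], [1.0])
        with pytest.raises(MCDAError):
            rank_fuzzy_vikor(f, 1.5)

    def test_cost_direction_awareness_on_raw_matrix(self):
        # lower is better on a cost column: A1 (cost 2) beats A0 (cost 4)
        f = crisp_matrix([[4.0], [2.0]], [1.0], directions=["cost"], normalized=False)
        r = rank_fuzzy_vikor(f)
        assert r.ranks["A1"] == 1

    def test_fuzzy_arithmetic_route_agrees_on_crisp_input(self):
        f = crisp_matrix([[1.0, 0.8], [0.4, 0.9], [0.6, 0.2]], [0.5, 0.5])
        a = rank_fuzzy_vikor(f, fuzzy_arithmetic=False)
        b = rank_fuzzy_vikor(f, fuzzy_arithmetic=True)
        for alt in f.alternatives:
            assert a.indices[alt] == pytest.approx(b.indices[alt], abs=1e-9)


class TestGoalProgramming:
    def test_goal_meeting_alternative_scores_zero(self):
        f = crisp_matrix([[1.0, 1.0], [0.5, 0.8]], [0.7, 0.3])
        r = rank_goal_programming(f)
        assert r.indices["A0"] == pytest.approx(0.0)

    def test_single_criterion_hand_example(self):
        f = crisp_matrix([[1.0], [0.5]], [1.0])
        r = rank_goal_programming(f)
        assert r.indices["A0"] == pytest.approx(0.0)
        assert r.indices["A1"] == pytest.approx(1.0)

    def test_closed_form_equals_lp_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            f = random_decision_matrix(rng, 3, 4)
            closed = rank_goal_programming(f, solver="closed_form")
            lp = rank_goal_programming(f, solver="lp")
            for a in f.alternatives:
                assert closed.indices[a] == pytest.approx(lp.indices[a], abs=1e-9)

    def test_weight_renormalization_leaves_index_unchanged(self):
        vals = [[1.0, 0.3, 0.9], [0.4, 1.0, 0.7]]
        r1 = rank_goal_programming(crisp_matrix(vals, [0.2, 0.3, 0.5]))
        # same relative weights, entered after renormalization from (2, 3, 5)
        w = np.array([2.0, 3.0, 5.0])
        r2 = rank_goal_programming(crisp_matrix(vals, w / w.sum()))
        for a in r1.indices:
            assert r1.indices[a] == pytest.approx(r2.indices[a], abs=1e-12)


class TestSharedInvariants:
    METHODS = (rank_fuzzy_topsis, rank_fuzzy_vikor, rank_goal_programming)

    @pytest.mark.parametrize("method", METHODS)
    def test_column_permutation_invariance(self, method):
        rng = np.random.default_rng(31)
        f = random_decision_matrix(rng, 3, 5)
        perm = rng.permutation(5)
        g = FuzzyDecisionMatrix(
            alternatives=f.alternatives,
            columns=tuple(f.columns[j] for j in perm),
            tfns=f.tfns[:, perm],
            weights=f.weights[perm],
            directions=tuple(f.directions[j] for j in perm),
            normalized=True,
        )
        ra, rb = method(f), method(g)
        for a in f.alternatives:
            assert ra.indices[a] == pytest.approx(rb.indices[a], abs=1e-12)

    @pytest.mark.parametrize("method", METHODS)
    def test_ranks_are_permutation_with_min_at_rank_one(self, method):
        rng = np.random.default_rng(37)
        for _ in range(20):
            f = random_decision_matrix(rng, 4, 3)
            r = method(f)
            assert sorted(r.ranks.values()) == [1, 2, 3, 4]
            best = min(r.indices, key=r.indices.get)
            assert r.indices[r.best] == pytest.approx(r.indices[best])

    @pytest.mark.parametrize("method", METHODS)
    def test_zero_weight_criterion_never_affects_index(self, method):
        rng = np.random.default_rng(41)
        f = random_decision_matrix(rng, 3, 4)
        extra = np.sort(rng.uniform(0, 1, size=(3, 1, 3)), axis=2)
        g = FuzzyDecisionMatrix(
            alternatives=f.alternatives,
            columns=(*f.columns, "junk"),
            tfns=np.concatenate([f.tfns, extra], axis=1),
            weights=np.concatenate([f.weights, [0.0]]),
            directions=(*f.directions, "benefit"),
            normalized=True,
        )
        ra, rb = method(f), method(g)
        for a in f.alternatives:
            assert ra.indices[a] == pytest.approx(rb.indices[a], abs=1e-12)

    @pytest.mark.parametrize("method", METHODS)
    def test_dominance_consistency(self, method):
        """A weakly dominant alternative (strict somewhere) must rank first."""
        rng = np.random.default_rng(43)
        for _ in range(200):
            m = int(rng.integers(2, 6))
            worse = rng.uniform(0.1, 0.9, size=m)
            margin = rng.uniform(0.02, 0.1, size=m)
            strict = rng.integers(0, m)
            better = np.minimum(worse + np.where(np.arange(m) == strict, margin, 0.0), 1.0)
            better = np.maximum(better, worse)
            f = crisp_matrix(np.vstack([better, worse]) , rng.dirichlet(np.ones(m)))
            assert method(f).ranks["A0"] == 1
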