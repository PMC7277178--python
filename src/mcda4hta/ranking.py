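"""Ranking engines: fuzzy TOPSIS, fuzzy VIKOR, goal programming.

All three report a per-alternative index where LOWER IS BETTER, so the
three methods can be read side by side.  TOPSIS therefore reports
d+/(d+ + d-) — the distance-to-ideal share — rather than the classical
closeness coefficient (its complement).  VIKOR reports Q, the blend of
group utility S and individual regret R with trade-off v.  Goal
programming reports the weighted sum of normalized absolute deviations
from the per-criterion goals, solved in closed form (the per-alternative
LP decouples; an LP-solver route is kept as a cross-check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .errors import MCDAError
from .fuzzy import TriangularFuzzyNumber, defuzzify, vertex_distance
from .performance import FuzzyDecisionMatrix

logger = logging.getLogger(__name__)

Method = Literal["fuzzy_topsis", "fuzzy_vikor", "goal_programming"]


@dataclass
class RankingResult:
    """Per-alternative index and rank for one method; rank 1 = best (minimal index)."""

    method: str
    indices: dict[str, float]
    ranks: dict[str, int]
    intermediates: dict[str, object] = field(default_factory=dict)
    config: dict[str, object] = field(default_factory=dict)

    @property
    def best(self) -> str:
        return min(self.indices, key=lambda a: (self.indices[a], self._order(a)))

    def _order(self, alt: str) -> int:
        return list(self.indices).index(alt)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "alternative": list(self.indices),
                "index": [self.indices[a] for a in self.indices],
                "rank": [self.ranks[a] for a in self.indices],
            }
        )


def _assign_ranks(alternatives, index_values) -> dict[str, int]:
    # stable sort: ties broken by document order of alternatives
    order = np.argsort(np.asarray(index_values), kind="stable")
    ranks = {}
    for pos, i in enumerate(order, start=1):
        ranks[alternatives[i]] = pos
    return ranks


def _defuzz_matrix(f: FuzzyDecisionMatrix, method: str) -> np.ndarray:
    t = f.tfns
    if method == "centroid":
        return t.mean(axis=2)
    return (t[..., 0] + 4.0 * t[..., 1] + t[..., 2]) / 6.0


def rank_fuzzy_topsis(f: FuzzyDecisionMatrix) -> RankingResult:
    """Distance-to-ideal index on the weighted normalized fuzzy matrix.

    v_ij = w_j * r_ij; per-column fuzzy positive ideal (w_j, w_j, w_j) and
    negative ideal (0, 0, 0); d+/d- are sums of vertex distances; index
    d+/(d+ + d-) in [0, 1], lower = better.
    """
    if not f.normalized:
        raise MCDAError("fuzzy TOPSIS requires a normalized matrix")
    n, m = len(f.alternatives), len(f.columns)
    v = f.tfns * f.weights[None, :, None]
    d_plus = np.zeros(n)
    d_minus = np.zeros(n)
    for i in range(n):
        for j in range(m):
            cell = TriangularFuzzyNumber(*v[i, j])
            w = f.weights[j]
            d_plus[i] += vertex_distance(cell, TriangularFuzzyNumber(w, w, w))
            d_minus[i] += vertex_distance(cell, TriangularFuzzyNumber(0.0, 0.0, 0.0))
    total = d_plus + d_minus
    indices = np.where(total > 0, d_plus / np.where(total > 0, total, 1.0), 0.5)
    if np.any(total == 0):
        logger.warning("degenerate single-point matrix: index 0.5 assigned by convention")
    idx = {a: float(x) for a, x in zip(f.alternatives, indices)}
    return RankingResult(
        method="fuzzy_topsis",
        indices=idx,
        ranks=_assign_ranks(f.alternatives, indices),
        intermediates={
            "d_plus": dict(zip(f.alternatives, map(float, d_plus))),
            "d_minus": dict(zip(f.alternatives, map(float, d_minus))),
        },
        config={"normalized": True},
    )


def rank_fuzzy_vikor(
    f: FuzzyDecisionMatrix,
    v: float = 0.5,
    *,
    defuzz: Literal["graded_mean", "centroid"] = "graded_mean",
    fuzzy_arithmetic: bool = False,
) -> RankingResult:
    """Compromise-ranking index Q blending group utility and max regret.

    Default route defuzzifies cells first and runs crisp VIKOR; the
    alternative route keeps TFN arithmetic for the per-criterion
    deviations and defuzzifies at the end.  v weighs group utility S
    against individual regret R (v = 0.5: consensus).  Direction-aware:
    on an unnormalized matrix cost columns take min as best.
    """
    if not (0.0 <= v <= 1.0):
        raise MCDAError(f"VIKOR v must lie in [0, 1], got {v}")
    n, m = len(f.alternatives), len(f.columns)
    if n < 2:
        raise MCDAError("VIKOR needs at least 2 alternatives")
    x = _defuzz_matrix(f, defuzz)
    best = np.empty(m)
    worst = np.empty(m)
    for j, direction in enumerate(f.directions):
        if direction == "cost":
            best[j], worst[j] = x[:, j].min(), x[:, j].max()
        else:
            best[j], worst[j] = x[:, j].max(), x[:, j].min()
    span = np.abs(best - worst)
    ok = span > 1e-15

    if fuzzy_arithmetic:
        # fuzzy deviation (f* (-) x)/span per column, then defuzzify S and R
        S = np.zeros(n)
        R = np.zeros(n)
        for i in range(n):
            summands = []
            for j in range(m):
                if not ok[j]:
                    summands.append(0.0)
                    continue
                cell = f.tfns[i, j]
                bi = int(np.argmax(x[:, j]) if f.directions[j] != "cost" else np.argmin(x[:, j]))
                fb = f.tfns[bi, j]
                if f.directions[j] == "cost":
                    dev = (cell[0] - fb[2], cell[1] - fb[1], cell[2] - fb[0])
                else:
                    dev = (fb[0] - cell[2], fb[1] - cell[1], fb[2] - cell[0])
                tfn = TriangularFuzzyNumber(*sorted(dev))
                summands.append(f.weights[j] * defuzzify(tfn, defuzz) / span[j])
            S[i] = float(np.sum(summands))
            R[i] = float(np.max(summands)) if summands else 0.0
        S = np.maximum(S, 0.0)
        R = np.maximum(R, 0.0)
    else:
        dev = np.abs(best[None, :] - x)  # distance from per-column best
        ratio = np.where(ok[None, :], dev / np.where(ok, span, 1.0)[None, :], 0.0)
        weighted = ratio * f.weights[None, :]
        S = weighted.sum(axis=1)
        R = weighted.max(axis=1) if m else np.zeros(n)

    s_star, s_minus = S.min(), S.max()
    r_star, r_minus = R.min(), R.max()
    q = np.zeros(n)
    if s_minus - s_star > 1e-15:
        q += v * (S - s_star) / (s_minus - s_star)
    if r_minus - r_star > 1e-15:
        q += (1.0 - v) * (R - r_star) / (r_minus - r_star)
    if s_minus - s_star <= 1e-15 and r_minus - r_star <= 1e-15:
        logger.warning("all alternatives identical under VIKOR; Q = 0 by convention")

    order = np.argsort(q, kind="stable")
    # compromise conditions, reported but never altering indices
    dq = 1.0 / (n - 1) if n > 1 else 1.0
    q_sorted = q[order]
    acceptable_advantage = bool(n >= 2 and q_sorted[1] - q_sorted[0] >= dq - 1e-12)
    best_alt = order[0]
    acceptable_stability = bool(
        S[best_alt] == S.min() or R[best_alt] == R.min()
    )
    idx = {a: float(val) for a, val in zip(f.alternatives, q)}
    return RankingResult(
        method="fuzzy_vikor",
        indices=idx,
        ranks=_assign_ranks(f.alternatives, q),
        intermediates={
            "S": dict(zip(f.alternatives, map(float, S))),
            "R": dict(zip(f.alternatives, map(float, R))),
            "Q": dict(zip(f.alternatives, map(float, q))),
            "acceptable_advantage": acceptable_advantage,
            "acceptable_stability": acceptable_stability,
        },
        config={"v": v, "defuzz": defuzz, "fuzzy_arithmetic": fuzzy_arithmetic},
    )


def _gp_closed_form(x: np.ndarray, w: np.ndarray, goals: np.ndarray, worsts: np.ndarray) -> np.ndarray:
    span = np.abs(goals - worsts)
    denom = np.where(span > 1e-15, span, 1.0)
    dev = np.abs(goals[None, :] - x) / denom[None, :]
    dev[:, span <= 1e-15] = 0.0
    return (dev * w[None, :]).sum(axis=1)


def _gp_via_lp(x: np.ndarray, w: np.ndarray, goals: np.ndarray, worsts: np.ndarray) -> np.ndarray:
    """Cross-check route: per alternative solve the deviation LP
    min sum_j w_j (d+_j + d-_j)/span_j  s.t.  x_ij + d-_j - d+_j = g_j, d >= 0."""
    from scipy.optimize import linprog

    n, m = x.shape
    span = np.abs(goals - worsts)
    denom = np.where(span > 1e-15, span, 1.0)
    coef = np.concatenate([w / denom, w / denom])  # d+ then d-
    coef = np.where(np.concatenate([span, span]) > 1e-15, coef, 0.0)
    out = np.empty(n)
    for i in range(n):
        a_eq = np.hstack([-np.eye(m), np.eye(m)])  # -d+ + d- = g - x
        b_eq = goals - x[i]
        res = linprog(coef, A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * (2 * m),
                      method="highs")
        if not res.success:
            raise MCDAError(f"GP LP failed for alternative {i}: {res.message}")
        out[i] = res.fun
    return out


def rank_goal_programming(
    f: FuzzyDecisionMatrix,
    *,
    defuzz: Literal["graded_mean", "centroid"] = "graded_mean",
    solver: Literal["closed_form", "lp"] = "closed_form",
) -> RankingResult:
    """Weighted normalized absolute deviation from per-criterion goals.

    Goals are the per-column direction-aware best defuzzified scores;
    deviations are scaled by the best-to-worst span so criteria with
    different units are commensurable.  Lower = better; 0 means every
    goal is met exactly.
    """
    x = _defuzz_matrix(f, defuzz)
    m = len(f.columns)
    goals = np.empty(m)
    worsts = np.empty(m)
    for j, direction in enumerate(f.directions):
        if direction == "cost":
            goals[j], worsts[j] = x[:, j].min(), x[:, j].max()
        else:
            goals[j], worsts[j] = x[:, j].max(), x[:, j].min()
    fn = _gp_via_lp if solver == "lp" else _gp_closed_form
    indices = fn(x, f.weights, goals, worsts)
    span = np.abs(goals - worsts)
    denom = np.where(span > 1e-15, span, 1.0)
    deviations = np.abs(goals[None, :] - x) / denom[None, :]
    deviations[:, span <= 1e-15] = 0.0
    idx = {a: float(val) for a, val in zip(f.alternatives, indices)}
    return RankingResult(
        method="goal_programming",
        indices=idx,
        ranks=_assign_ranks(f.alternatives, indices),
        intermediates={
            "goals": dict(zip(f.columns, map(float, goals))),
            "deviations": {
                a: dict(zip(f.columns, map(float, deviations[i])))
                for i, a in enumerate(f.alternatives)
            },
        },
        config={"defuzz": defuzz, "solver": solver},
    )
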