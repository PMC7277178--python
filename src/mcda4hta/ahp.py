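"""Analytic Hierarchy Process: pairwise judgments to criterion weights.

A decision panel expresses relative importance of sibling criteria on
Saaty's 1-9 ratio scale; each parent node yields one reciprocal matrix per
respondent.  Individual judgments are pooled by element-wise geometric mean
(aggregation of individual judgments, AIJ) or, alternatively, individual
weight vectors are averaged (aggregation of individual priorities, AIP).
Local weights come from the principal right eigenvector; coherence is
monitored through Saaty's consistency ratio (CR), with CR > 0.1 flagged.
Global leaf weights are products of local weights along the root-to-leaf
path and sum to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import ConvergenceError, MatrixError
from .hierarchy import ROOT_ID, CriteriaHierarchy
from .hierarchy import plan_elicitation as _plan

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

CR_THRESHOLD = 0.1

_SAATY_VALUES = np.array(
    [1 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)


class ConsistencyWarning(UserWarning):
    """Emitted when a matrix's consistency ratio exceeds the 0.1 convention."""


@dataclass
class PairwiseComparisonMatrix:
    """Reciprocal ratio matrix of sibling comparisons.

    ``values[i, j]`` is how many times criterion i dominates criterion j;
    the diagonal is 1 and ``values[j, i] = 1/values[i, j]`` to 1e-9.
    """

    matrix_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n) or n < 2:
            raise MatrixError(f"{self.matrix_id}: matrix must be square, order >= 2")
        if not np.all(self.values > 0):
            raise MatrixError(f"{self.matrix_id}: entries must be positive")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise MatrixError(f"{self.matrix_id}: diagonal must be 1")
        if not np.allclose(self.values * self.values.T, 1.0, atol=1e-9):
            raise MatrixError(f"{self.matrix_id}: reciprocity violated (a_ij * a_ji != 1)")

    @property
    def order(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_upper(cls, matrix_id: str, order: int,
                   upper: Mapping[tuple[int, int], float]) -> "PairwiseComparisonMatrix":
        """Build from the strict upper triangle; reciprocals auto-filled."""
        m = np.ones((order, order))
        for (i, j), v in upper.items():
            if not (0 <= i < j < order):
                raise MatrixError(f"{matrix_id}: ({i},{j}) not strictly upper-triangular")
            if v <= 0:
                raise MatrixError(f"{matrix_id}: ratio must be positive, got {v}")
            m[i, j] = v
            m[j, i] = 1.0 / v
        return cls(matrix_id, m)


@dataclass
class JudgmentSet:
    """One respondent's filled matrices, keyed by matrix id."""

    respondent_id: str
    matrices: dict[str, PairwiseComparisonMatrix]


@dataclass
class WeightVector:
    """Non-negative weights over node ids; local (siblings) or global (leaves).

    Either scope sums to one within 1e-9.
    """

    weights: dict[str, float]
    scope: Literal["local", "global"] = "local"

    def __post_init__(self) -> None:
        for nid, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {nid!r}")
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.scope} weights sum to {total}, expected 1")

    def __getitem__(self, nid: str) -> float:
        return self.weights[nid]

    def as_series(self):
        import pandas as pd

        return pd.Series(self.weights, name="weight")


def aggregate_judgments(
    judgments: Sequence[PairwiseComparisonMatrix],
) -> PairwiseComparisonMatrix:
    """Pool respondents' matrices by element-wise geometric mean.

    The geometric mean is the unique pooling rule that preserves
    reciprocity exactly: gm(a_ij) * gm(a_ji) = gm(a_ij * a_ji) = 1.
    """
    if not judgments:
        raise MatrixError("no judgments to aggregate")
    mid = judgments[0].matrix_id
    n = judgments[0].order
    for m in judgments[1:]:
        if m.matrix_id != mid:
            raise MatrixError(f"mixed matrix ids: {mid!r} vs {m.matrix_id!r}")
        if m.order != n:
            raise MatrixError(f"{mid}: mismatched orders {n} vs {m.order}")
    logs = np.mean([np.log(m.values) for m in judgments], axis=0)
    agg = np.exp(logs)
    # symmetrize exactly against floating-point drift
    iu = np.triu_indices(n, 1)
    agg[(iu[1], iu[0])] = 1.0 / agg[iu]
    np.fill_diagonal(agg, 1.0)
    return PairwiseComparisonMatrix(mid, agg)


def principal_weights(
    m: PairwiseComparisonMatrix,
    *,
    method: Literal["eigenvector", "geometric_mean"] = "eigenvector",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Local priority vector and principal eigenvalue lambda_max.

    Default is power iteration on the matrix (right principal eigenvector,
    normalized to sum 1); ``geometric_mean`` is the row geometric-mean
    approximation, exact for consistent matrices.
    """
    a = m.values
    n = m.order
    if method == "geometric_mean":
        w = np.exp(np.mean(np.log(a), axis=1))
        w /= w.sum()
        lam = float(np.mean((a @ w) / w))
        return w, lam
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        aw = a @ w
        w_new = aw / aw.sum()
        lam = float(np.mean(aw / w))
        if np.max(np.abs(w_new - w)) < tol:
            return w_new, float(np.mean((a @ w_new) / w_new))
        w = w_new
    raise ConvergenceError(
        f"{m.matrix_id}: power iteration did not converge in {max_iter} iterations"
    )


def consistency_ratio(m: PairwiseComparisonMatrix) -> float:
    """Saaty's CR = CI / RI(n), with CI = (lambda_max - n)/(n - 1).

    Orders 1-2 are consistent by construction and return 0; orders above
    10 are rejected (no tabulated random index).
    """
    n = m.order
    if n <= 2:
        return 0.0
    if n not in RANDOM_INDEX:
        raise MatrixError(f"{m.matrix_id}: no random index for order {n} (max 10)")
    _, lam = principal_weights(m)
    ci = (lam - n) / (n - 1)
    return max(ci, 0.0) / RANDOM_INDEX[n]


def derive_local_weights(
    h: CriteriaHierarchy,
    judgment_sets: Sequence[JudgmentSet],
    *,
    aggregation: Literal["judgments", "priorities"] = "judgments",
    eigen_method: Literal["eigenvector", "geometric_mean"] = "eigenvector",
    strict_cr: bool = False,
) -> tuple[dict[str, WeightVector], dict[str, float]]:
    """Local weight vector and CR for every planned matrix.

    ``judgments`` pools matrices first (geometric mean) then extracts one
    eigenvector; ``priorities`` extracts per-respondent eigenvectors and
    arithmetically averages them.  Respondents missing a matrix are skipped
    with the count implied by the pool; full absence is an error.  CR above
    0.1 warns (or raises under ``strict_cr``); the reported CR is that of
    the pooled matrix.
    """
    from .errors import ConsistencyError

    plan = _plan(h)
    locals_: dict[str, WeightVector] = {}
    crs: dict[str, float] = {}
    for mid, kids in plan.matrices:
        pool = [js.matrices[mid] for js in judgment_sets if mid in js.matrices]
        if not pool:
            raise MatrixError(f"no respondent provided matrix {mid!r}")
        for m in pool:
            if m.order != len(kids):
                raise MatrixError(
                    f"{mid}: matrix order {m.order} != {len(kids)} planned children"
                )
        agg = aggregate_judgments(pool)
        cr = consistency_ratio(agg)
        crs[mid] = cr
        if cr > CR_THRESHOLD:
            msg = f"matrix {mid!r}: CR {cr:.3f} exceeds {CR_THRESHOLD}"
            if strict_cr:
                raise ConsistencyError(msg)
            warnings.warn(msg, ConsistencyWarning, stacklevel=2)
        if aggregation == "priorities":
            vecs = [principal_weights(m, method=eigen_method)[0] for m in pool]
            w = np.mean(vecs, axis=0)
            w /= w.sum()
        else:
            w, _ = principal_weights(agg, method=eigen_method)
        locals_[mid] = WeightVector(dict(zip(kids, map(float, w))), scope="local")
    return locals_, crs


def synthesize_global_weights(
    h: CriteriaHierarchy, local_weights: Mapping[str, WeightVector]
) -> WeightVector:
    """Global leaf weights: product of local weights along the root path.

    Parents with a single child contribute factor 1.  The result sums to 1
    by telescoping of the per-sibling normalizations.
    """
    plan = _plan(h)
    for mid, _ in plan.matrices:
        if mid not in local_weights:
            raise MatrixError(f"missing local weight vector for planned matrix {mid!r}")

    def local(nid: str) -> float:
        parent = h.nodes[nid].parent_id
        if len(h.children(parent)) == 1:
            return 1.0
        return local_weights[parent].weights[nid]

    out: dict[str, float] = {}
    for leaf in h.leaves():
        w = 1.0
        for nid in h.path_to_root(leaf.id):
            w *= local(nid)
        out[leaf.id] = w
    total = sum(out.values())
    if abs(total - 1.0) > 1e-6:
        raise MatrixError(f"global leaf weights sum to {total}; incomplete local set?")
    out = {k: v / total for k, v in out.items()}
    return WeightVector(out, scope="global")


def snap_to_saaty(x: float) -> float:
    """Nearest value (in log space) in {1/9..1/2, 1..9}."""
    return float(_SAATY_VALUES[np.argmin(np.abs(np.log(_SAATY_VALUES) - math.log(x)))])
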