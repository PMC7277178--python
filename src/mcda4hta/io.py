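"""CSV interchange for questionnaire responses and weight vectors."""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ahp import JudgmentSet, PairwiseComparisonMatrix, WeightVector
from .errors import MatrixError, TableError
from .hierarchy import CriteriaHierarchy, ElicitationPlan, plan_elicitation

RESPONSE_COLUMNS = ["respondent_id", "matrix_id", "row_node", "col_node", "saaty_value"]


def parse_saaty(token: str) -> float:
    """Parse '3', '1/3' or a float literal into a positive ratio."""
    token = str(token).strip()
    try:
        value = float(Fraction(token)) if "/" in token else float(token)
    except (ValueError, ZeroDivisionError):
        raise MatrixError(f"unparseable Saaty value {token!r}") from None
    if value <= 0:
        raise MatrixError(f"Saaty value must be positive, got {token!r}")
    return value


def format_saaty(value: float) -> str:
    """Render a ratio as 'k' or '1/k' when it is (close to) a Saaty level."""
    for k in range(1, 10):
        if abs(value - k) < 1e-9:
            return str(k)
        if abs(value - 1.0 / k) < 1e-9:
            return f"1/{k}"
    return f"{value:.12g}"


def load_responses(
    path: str | Path | pd.DataFrame, plan: ElicitationPlan
) -> list[JudgmentSet]:
    """Read the long-format questionnaire CSV into per-respondent matrices.

    Rows carry one judged pair each; reciprocals are auto-filled, and a
    pair judged twice with conflicting ratios is rejected.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, dtype=str)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"responses file lacks columns {sorted(missing)}")
    children = dict(plan.matrices)
    sets: list[JudgmentSet] = []
    for rid, group in df.groupby("respondent_id", sort=False):
        matrices: dict[str, PairwiseComparisonMatrix] = {}
        for mid, rows in group.groupby("matrix_id", sort=False):
            if mid not in children:
                raise TableError(f"respondent {rid}: unknown matrix id {mid!r}")
            kids = list(children[mid])
            index = {k: i for i, k in enumerate(kids)}
            upper: dict[tuple[int, int], float] = {}
            for row in rows.itertuples():
                try:
                    i, j = index[row.row_node], index[row.col_node]
                except KeyError as exc:
                    raise TableError(
                        f"respondent {rid}, matrix {mid}: node {exc} not a child"
                    ) from None
                if i == j:
                    continue
                v = parse_saaty(row.saaty_value)
                key, val = ((i, j), v) if i < j else ((j, i), 1.0 / v)
                if key in upper and abs(upper[key] - val) > 1e-9:
                    raise TableError(
                        f"respondent {rid}, matrix {mid}: conflicting duplicate "
                        f"judgment for pair ({row.row_node}, {row.col_node})"
                    )
                upper[key] = val
            expected = len(kids) * (len(kids) - 1) // 2
            if len(upper) != expected:
                raise TableError(
                    f"respondent {rid}, matrix {mid}: {len(upper)} of {expected} "
                    "pairs judged"
                )
            matrices[str(mid)] = PairwiseComparisonMatrix.from_upper(
                str(mid), len(kids), upper
            )
        sets.append(JudgmentSet(str(rid), matrices))
    if not sets:
        raise TableError("responses file holds no judgments")
    return sets


def write_responses(
    sets: Sequence[JudgmentSet], plan: ElicitationPlan, path: str | Path
) -> None:
    rows = []
    children = dict(plan.matrices)
    for js in sets:
        for mid, matrix in js.matrices.items():
            kids = children[mid]
            for i in range(matrix.order):
                for j in range(i + 1, matrix.order):
                    rows.append(
                        {
                            "respondent_id": js.respondent_id,
                            "matrix_id": mid,
                            "row_node": kids[i],
                            "col_node": kids[j],
                            "saaty_value": format_saaty(matrix.values[i, j]),
                        }
                    )
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def write_weights(
    locals_: Mapping[str, WeightVector],
    global_w: WeightVector,
    crs: Mapping[str, float],
    path: str | Path,
) -> None:
    """Persist local + global weights and per-matrix CR in one CSV."""
    rows = []
    for mid, wv in locals_.items():
        for nid, w in wv.weights.items():
            rows.append(
                {
                    "scope": "local",
                    "matrix_id": mid,
                    "node_id": nid,
                    "weight": f"{w:.12g}",
                    "cr": f"{crs.get(mid, float('nan')):.6g}",
                }
            )
    for nid, w in global_w.weights.items():
        rows.append(
            {"scope": "global", "matrix_id": "", "node_id": nid,
             "weight": f"{w:.12g}", "cr": ""}
        )
    pd.DataFrame(rows, columns=["scope", "matrix_id", "node_id", "weight", "cr"]).to_csv(
        path, index=False
    )


def load_global_weights(path: str | Path) -> WeightVector:
    df = pd.read_csv(path, dtype={"node_id": str})
    rows = df[df["scope"] == "global"]
    if rows.empty:
        raise TableError(f"{path}: no global-scope weights found")
    return WeightVector(
        {str(r.node_id): float(r.weight) for r in rows.itertuples()}, scope="global"
    )
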