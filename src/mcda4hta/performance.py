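"""Evidence table handling: load, validate, fuzzify, normalize.

The performance table holds the alternatives-by-leaf-criteria scores
extracted from an HTA report.  Cells are typed per column (numeric, yes/no,
linguistic) with the type and the benefit/cost direction owned by the
hierarchy, not the table header.  Fuzzification embeds all cells as
triangular fuzzy numbers and attaches the renormalized global weights of
the surviving columns; normalization maps every column onto [0, 1] support
with linear max scaling for benefit columns and reciprocal min scaling for
cost columns (so that after normalization, higher is uniformly better).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, TableError
from .fuzzy import LinguisticScale, TriangularFuzzyNumber, encode_score, get_scale
from .hierarchy import CriteriaHierarchy

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "na", "n/a", "nan", "none", "missing", "-"}


@dataclass
class PerformanceTable:
    """Raw alternatives x leaf-criteria scores bound to a hierarchy."""

    alternatives: tuple[str, ...]
    columns: tuple[str, ...]
    cells: pd.DataFrame  # index alternatives, columns leaf ids, object dtype
    kinds: dict[str, str]
    directions: dict[str, str]

    def is_missing(self, alt: str, col: str) -> bool:
        v = self.cells.at[alt, col]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return True
        return str(v).strip().lower() in MISSING_TOKENS


@dataclass
class FuzzyDecisionMatrix:
    """Fuzzified (optionally normalized) decision matrix with column weights.

    ``tfns`` has shape (n_alternatives, n_columns, 3) holding (l, m, u).
    Weights are the global leaf weights restricted to the present columns
    and renormalized to sum 1.
    """

    alternatives: tuple[str, ...]
    columns: tuple[str, ...]
    tfns: np.ndarray
    weights: np.ndarray
    directions: tuple[str, ...]
    normalized: bool = False
    scale_name: str = "default7"
    dropped_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.tfns = np.asarray(self.tfns, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n, m = len(self.alternatives), len(self.columns)
        if self.tfns.shape != (n, m, 3):
            raise TableError(f"tfns shape {self.tfns.shape} != {(n, m, 3)}")
        if self.weights.shape != (m,):
            raise TableError("one weight per column required")
        if m and abs(self.weights.sum() - 1.0) > 1e-9:
            raise TableError(f"column weights sum to {self.weights.sum()}, expected 1")
        if np.any(self.tfns[..., 0] > self.tfns[..., 1] + 1e-12) or np.any(
            self.tfns[..., 1] > self.tfns[..., 2] + 1e-12
        ):
            raise TableError("invalid TFN (l <= m <= u violated) in matrix")

    def cell(self, i: int, j: int) -> TriangularFuzzyNumber:
        return TriangularFuzzyNumber(*self.tfns[i, j])


def _read_csv_with_comments(source: str | Path) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """Parse the table CSV; '#kind'/'#direction' annotation rows are optional."""
    raw = pd.read_csv(source, header=0, dtype=str, keep_default_na=False)
    meta: dict[str, dict[str, str]] = {}
    first = raw.columns[0]
    body_rows = []
    for _, row in raw.iterrows():
        tag = str(row[first]).strip()
        if tag.startswith("#"):
            meta[tag.lstrip("#").strip().lower()] = {
                c: str(row[c]).strip() for c in raw.columns[1:]
            }
        else:
            body_rows.append(row)
    body = pd.DataFrame(body_rows, columns=raw.columns)
    return body, meta


def load_table(source: str | Path | pd.DataFrame, h: CriteriaHierarchy) -> PerformanceTable:
    """Load and bind a performance table to the hierarchy's leaves.

    Tabular layout: first column alternative label, remaining columns leaf
    ids.  Annotation rows ``#kind`` / ``#direction`` are accepted but must
    agree with the hierarchy (single source of truth).
    """
    if isinstance(source, pd.DataFrame):
        body, meta = source.astype(str), {}
        body = body.copy()
    else:
        body, meta = _read_csv_with_comments(source)
    first = body.columns[0]
    col_ids = [str(c) for c in body.columns[1:]]
    leaf_ids = {leaf.id: leaf for leaf in h.leaves()}
    for cid in col_ids:
        if cid not in leaf_ids:
            raise TableError(f"column {cid!r} is not a leaf of the hierarchy")
    kinds = {cid: leaf_ids[cid].data_kind for cid in col_ids}
    directions = {cid: leaf_ids[cid].direction for cid in col_ids}
    for key, attr in (("kind", kinds), ("direction", directions)):
        if key in meta:
            for cid in col_ids:
                declared = meta[key].get(cid, "").strip().lower()
                if declared and declared != attr[cid]:
                    raise TableError(
                        f"column {cid!r}: table declares {key}={declared!r} but the "
                        f"hierarchy says {attr[cid]!r}"
                    )
    alts = [str(a).strip() for a in body[first]]
    if len(set(alts)) != len(alts):
        raise TableError(f"duplicate alternative labels in {sorted(alts)}")
    cells = body.set_index(first)
    cells.index = [str(a).strip() for a in cells.index]
    cells.columns = col_ids
    # eager per-cell type check for numeric columns (named coordinates on failure)
    for cid in col_ids:
        if kinds[cid] == "numeric":
            for alt in alts:
                v = str(cells.at[alt, cid]).strip().lower()
                if v in MISSING_TOKENS:
                    continue
                try:
                    float(v)
                except ValueError:
                    raise TableError(
                        f"row {alt!r}, column {cid!r}: non-numeric value {cells.at[alt, cid]!r}"
                    ) from None
    table = PerformanceTable(tuple(alts), tuple(col_ids), cells, kinds, directions)
    for cid in col_ids:
        if all(table.is_missing(alt, cid) for alt in alts):
            raise TableError(f"column {cid!r} is missing for every alternative")
    return table


def fuzzify_table(
    t: PerformanceTable,
    global_weights: Mapping[str, float],
    scale: LinguisticScale | None = None,
) -> FuzzyDecisionMatrix:
    """Encode every cell as a TFN and attach renormalized column weights.

    A column missing for any alternative is dropped entirely (an MCDA
    comparison needs evidence on all comparators) and the weights of the
    surviving columns are renormalized; the event is logged.
    """
    scale = scale or get_scale()
    keep, dropped = [], []
    for cid in t.columns:
        if any(t.is_missing(alt, cid) for alt in t.alternatives):
            dropped.append(cid)
            logger.warning(
                "column %r dropped: missing for at least one alternative; "
                "weights renormalized over remaining columns", cid,
            )
        else:
            keep.append(cid)
    if not keep:
        raise TableError("all columns dropped; nothing to rank")
    tfns = np.empty((len(t.alternatives), len(keep), 3))
    for j, cid in enumerate(keep):
        for i, alt in enumerate(t.alternatives):
            try:
                tfn = encode_score(t.cells.at[alt, cid], t.kinds[cid], scale)
            except Exception as exc:
                raise TableError(f"row {alt!r}, column {cid!r}: {exc}") from exc
            tfns[i, j] = tfn.astuple()
    w = np.array([float(global_weights.get(cid, 0.0)) for cid in keep])
    if w.sum() <= 0:
        raise TableError("surviving columns carry zero total weight")
    w = w / w.sum()
    return FuzzyDecisionMatrix(
        alternatives=t.alternatives,
        columns=tuple(keep),
        tfns=tfns,
        weights=w,
        directions=tuple(t.directions[c] for c in keep),
        normalized=False,
        scale_name=scale.name,
        dropped_columns=tuple(dropped),
    )


def normalize_matrix(f: FuzzyDecisionMatrix) -> FuzzyDecisionMatrix:
    """Linear max/min normalization onto [0, 1] support, direction-aware.

    Benefit column with c* = max_i u_ij: (l, m, u) -> (l, m, u)/c*.
    Cost column with a- = min_i l_ij:    (l, m, u) -> (a-/u, a-/m, a-/l).
    After this every column behaves as a benefit criterion with at least
    one alternative attaining upper support 1.
    """
    if f.normalized:
        return f
    out = np.empty_like(f.tfns)
    for j, (cid, direction) in enumerate(zip(f.columns, f.directions)):
        col = f.tfns[:, j, :]
        if direction == "benefit":
            c_star = col[:, 2].max()
            if c_star <= 0:
                raise NormalizationError(
                    f"column {cid!r}: max upper support {c_star} <= 0; "
                    "apply an affine pre-shift to make scores positive"
                )
            out[:, j, :] = col / c_star
        else:
            a_minus = col[:, 0].min()
            if a_minus <= 0:
                raise NormalizationError(
                    f"column {cid!r}: cost scores must be strictly positive "
                    f"(min lower support {a_minus}); apply an affine pre-shift"
                )
            out[:, j, 0] = a_minus / col[:, 2]
            out[:, j, 1] = a_minus / col[:, 1]
            out[:, j, 2] = a_minus / col[:, 0]
    return replace(
        f,
        tfns=out,
        directions=tuple("benefit" for _ in f.columns),
        normalized=True,
    )
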