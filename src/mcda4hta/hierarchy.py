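"""Criteria hierarchy for HTA multi-criteria decision analysis.

The decision problem is structured as a goal on top of up to four levels of
criteria, mirroring how the nine domains of the HTA Core Model (health
problem, technical characteristics, safety, clinical effectiveness, costs,
ethical, organizational, social, legal aspects) decompose into topics and
issues.  Level-1 nodes are the main criteria; leaves carry an optimization
direction (benefit/cost) and the kind of evidence scored against them
(numeric, binary yes/no, or a 7-level linguistic term).

The module also derives the *elicitation plan*: which pairwise-comparison
matrices a decision panel must fill in, grouped into questionnaires (one
instrument for the main criteria plus one per main-criterion subtree).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    DepthError,
    DuplicateIdError,
    HierarchyError,
    LeafAttributeError,
    OrphanNodeError,
)

ROOT_ID = "__goal__"
MAX_DEPTH = 4

DIRECTIONS = ("benefit", "cost")
DATA_KINDS = ("numeric", "binary", "linguistic")


@dataclass(frozen=True)
class CriterionNode:
    """A single criterion in the hierarchy.

    ``direction`` and ``data_kind`` are present iff the node is a leaf;
    internal nodes only aggregate their children's weights.
    """

    id: str
    label: str
    level: int
    parent_id: str
    direction: str | None = None
    data_kind: str | None = None

    @property
    def is_main(self) -> bool:
        return self.level == 1


class CriteriaHierarchy:
    """Validated criteria tree: single root, acyclic, depth <= 4.

    Children keep document order everywhere so matrix indexing and leaf
    ordering are reproducible across runs.
    """

    def __init__(self, goal: str, nodes: Sequence[CriterionNode]):
        self.goal = goal
        self.nodes: dict[str, CriterionNode] = {}
        self._children: dict[str, list[str]] = {ROOT_ID: []}
        for node in nodes:
            if node.id in self.nodes or node.id == ROOT_ID:
                raise DuplicateIdError(f"duplicate criterion id {node.id!r}")
            self.nodes[node.id] = node
            self._children.setdefault(node.id, [])
        for node in nodes:  # second pass: parents may appear later in input
            if node.parent_id != ROOT_ID and node.parent_id not in self.nodes:
                raise OrphanNodeError(
                    f"node {node.id!r} cites missing parent {node.parent_id!r}"
                )
            self._children[node.parent_id].append(node.id)
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for node in self.nodes.values():
            parent_level = 0 if node.parent_id == ROOT_ID else self.nodes[node.parent_id].level
            if node.level != parent_level + 1:
                raise HierarchyError(
                    f"node {node.id!r} has level {node.level}, expected "
                    f"{parent_level + 1} (child of level-{parent_level} parent)"
                )
            if node.level > MAX_DEPTH:
                raise DepthError(f"node {node.id!r} exceeds maximum depth {MAX_DEPTH}")
            if self.is_leaf(node.id):
                if node.direction not in DIRECTIONS:
                    raise LeafAttributeError(
                        f"leaf {node.id!r} missing/invalid direction {node.direction!r}"
                    )
                if node.data_kind not in DATA_KINDS:
                    raise LeafAttributeError(
                        f"leaf {node.id!r} missing/invalid data_kind {node.data_kind!r}"
                    )
            else:
                if node.direction is not None or node.data_kind is not None:
                    raise LeafAttributeError(
                        f"internal node {node.id!r} must not carry direction/data_kind"
                    )
        # reachability is structural: every node was attached to a resolved parent,
        # and the level rule forbids cycles (a cycle cannot increase level forever).

    # -- queries ---------------------------------------------------------

    def children(self, node_id: str) -> list[str]:
        return list(self._children.get(node_id, []))

    def is_leaf(self, node_id: str) -> bool:
        return not self._children.get(node_id)

    @property
    def main_criteria(self) -> list[str]:
        return list(self._children[ROOT_ID])

    def leaves(self) -> list[CriterionNode]:
        """Leaves in depth-first document order (stable across runs)."""
        out: list[CriterionNode] = []

        def walk(nid: str) -> None:
            kids = self._children.get(nid, [])
            if nid != ROOT_ID and not kids:
                out.append(self.nodes[nid])
            for kid in kids:
                walk(kid)

        walk(ROOT_ID)
        return out

    def level_counts(self) -> dict[int, int]:
        """Node count at each depth, the goal excluded."""
        counts: dict[int, int] = {}
        for node in self.nodes.values():
            counts[node.level] = counts.get(node.level, 0) + 1
        return dict(sorted(counts.items()))

    def path_to_root(self, node_id: str) -> list[str]:
        """Ids from the node up to (excluding) the goal."""
        path = [node_id]
        while self.nodes[path[-1]].parent_id != ROOT_ID:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def subtree_ids(self, node_id: str) -> list[str]:
        out = [node_id]
        for kid in self._children.get(node_id, []):
            out.extend(self.subtree_ids(kid))
        return out

    # -- serialization ---------------------------------------------------

    def to_document(self) -> dict:
        def build(nid: str) -> dict:
            node = self.nodes[nid]
            doc: dict = {"id": node.id, "label": node.label}
            if self.is_leaf(nid):
                doc["direction"] = node.direction
                doc["kind"] = node.data_kind
            else:
                doc["children"] = [build(k) for k in self._children[nid]]
            return doc

        return {
            "goal": self.goal,
            "children": [build(k) for k in self._children[ROOT_ID]],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_document()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))


@dataclass(frozen=True)
class ElicitationPlan:
    """Pairwise matrices the panel must judge, grouped into questionnaires.

    One matrix per parent with >= 2 children; single children inherit local
    weight 1 without a matrix.  Instruments: one for the main criteria,
    plus one per main criterion covering its subtree (possibly empty), so
    questionnaire count is structurally 1 + number of main criteria.
    """

    matrices: tuple[tuple[str, tuple[str, ...]], ...]
    questionnaires: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def matrix_ids(self) -> list[str]:
        return [parent for parent, _ in self.matrices]

    def children_of(self, matrix_id: str) -> tuple[str, ...]:
        for parent, kids in self.matrices:
            if parent == matrix_id:
                return kids
        raise KeyError(matrix_id)

    def to_frame(self):
        import pandas as pd

        rows = []
        q_of = {}
        for qid, mids in self.questionnaires:
            for mid in mids:
                q_of[mid] = qid
        for parent, kids in self.matrices:
            rows.append(
                {
                    "matrix_id": parent,
                    "parent_id": parent,
                    "child_ids": ";".join(kids),
                    "questionnaire_id": q_of[parent],
                }
            )
        return pd.DataFrame(rows, columns=["matrix_id", "parent_id", "child_ids", "questionnaire_id"])


def plan_elicitation(h: CriteriaHierarchy) -> ElicitationPlan:
    """Derive the pairwise matrices and questionnaire grouping for ``h``.

    Matrix ids equal the parent node id (the goal's matrix uses the root
    sentinel); ordering is document order throughout.
    """
    matrices: list[tuple[str, tuple[str, ...]]] = []

    def collect(nid: str) -> None:
        kids = h.children(nid)
        if len(kids) >= 2:
            matrices.append((nid, tuple(kids)))
        for kid in kids:
            collect(kid)

    collect(ROOT_ID)

    questionnaires: list[tuple[str, tuple[str, ...]]] = [
        ("Q-main", (ROOT_ID,) if len(h.main_criteria) >= 2 else ())
    ]
    for main in h.main_criteria:
        members = tuple(
            parent for parent, _ in matrices
            if parent != ROOT_ID and main in (parent, *h.path_to_root(parent))
        )
        questionnaires.append((f"Q-{main}", members))
    return ElicitationPlan(tuple(matrices), tuple(questionnaires))


# -- document IO ---------------------------------------------------------


def _parse_node(doc: Mapping, parent_id: str, level: int, out: list[CriterionNode]) -> None:
    if "id" not in doc:
        raise HierarchyError(f"node under {parent_id!r} lacks an 'id'")
    nid = str(doc["id"])
    declared = doc.get("level")
    if declared is not None and int(declared) != level:
        raise HierarchyError(
            f"node {nid!r} declares level {declared} but nests at level {level}"
        )
    kids = doc.get("children") or []
    out.append(
        CriterionNode(
            id=nid,
            label=str(doc.get("label", nid)),
            level=level,
            parent_id=parent_id,
            direction=doc.get("direction"),
            data_kind=doc.get("kind", doc.get("data_kind")),
        )
    )
    for kid in kids:
        _parse_node(kid, nid, level + 1, out)


def hierarchy_from_document(doc: Mapping) -> CriteriaHierarchy:
    """Build a validated hierarchy from a nested mapping.

    Schema: ``{"goal": str, "children": [{"id", "label", "direction",
    "kind", "children": [...]}, ...]}``; ``level`` is optional and, when
    present, must agree with the nesting depth.
    """
    if "children" not in doc:
        raise HierarchyError("hierarchy document lacks 'children'")
    nodes: list[CriterionNode] = []
    for kid in doc["children"]:
        _parse_node(kid, ROOT_ID, 1, nodes)
    return CriteriaHierarchy(str(doc.get("goal", "Goal")), nodes)


def load_hierarchy(source: str | Path) -> CriteriaHierarchy:
    """Load a hierarchy from a JSON or YAML file (dialect auto-detected)."""
    text = Path(source).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise HierarchyError(f"{source}: top level must be a mapping")
    return hierarchy_from_document(doc)


def level_counts(h: CriteriaHierarchy) -> dict[int, int]:
    return h.level_counts()


def leaves(h: CriteriaHierarchy) -> list[CriterionNode]:
    return h.leaves()
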