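import numpy as np
import pytest

from mcda4hta import (
    CriteriaHierarchy,
    CriterionNode,
    FuzzyDecisionMatrix,
)
from mcda4hta.hierarchy import ROOT_ID


@pytest.fixture
def minimal_hierarchy() -> CriteriaHierarchy:
    """Goal + two main-criterion leaves: the smallest valid tree."""
    return CriteriaHierarchy(
        "goal",
        [
            CriterionNode("A", "A", 1, ROOT_ID, "benefit", "numeric"),
            CriterionNode("B", "B", 1, ROOT_ID, "benefit", "numeric"),
        ],
    )


@pytest.fixture
def chain_hierarchy() -> CriteriaHierarchy:
    """goal -> A -> A1: single children everywhere, no sibling pairs."""
    return CriteriaHierarchy(
        "goal",
        [
            CriterionNode("A", "A", 1, ROOT_ID),
            CriterionNode("A1", "A1", 2, "A", "benefit", "numeric"),
        ],
    )


@pytest.fixture
def two_level_hierarchy() -> CriteriaHierarchy:
    """Two mains, the first with two numeric leaves (mixed directions)."""
    return CriteriaHierarchy(
        "goal",
        [
            CriterionNode("A", "A", 1, ROOT_ID),
            CriterionNode("A1", "A1", 2, "A", "benefit", "numeric"),
            CriterionNode("A2", "A2", 2, "A", "cost", "numeric"),
            CriterionNode("B", "B", 1, ROOT_ID, "benefit", "numeric"),
        ],
    )


def random_decision_matrix(
    rng: np.random.Generator, n_alt: int = 2, n_col: int = 4, normalized: bool = True
) -> FuzzyDecisionMatrix:
    """Random valid normalized fuzzy decision matrix for property tests."""
    pts = np.sort(rng.uniform(0.05, 1.0, size=(n_alt, n_col, 3)), axis=2)
    if normalized:
        pts = pts / pts[..., 2].max(axis=0)[None, :, None]
    w = rng.dirichlet(np.ones(n_col))
    return FuzzyDecisionMatrix(
        alternatives=tuple(f"A{i}" for i in range(n_alt)),
        columns=tuple(f"c{j}" for j in range(n_col)),
        tfns=pts,
        weights=w,
        directions=("benefit",) * n_col,
        normalized=normalized,
    )
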