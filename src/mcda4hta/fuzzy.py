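"""Triangular fuzzy numbers and the encodings of mixed-type evidence.

HTA reports score criteria three ways: numeric measurements, yes/no
judgments, and qualitative statements on a 7-level linguistic scale.  All
three are embedded into triangular fuzzy numbers (l, m, u): numerics and
yes/no degenerately (x, x, x) with yes -> 1 and no -> 0, linguistic terms
through a scale table mapping each term to its fuzzy support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import EncodingError


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Fuzzy quantity with membership rising linearly l->m and falling m->u."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(f"TFN requires l <= m <= u, got {(self.l, self.m, self.u)}")

    @classmethod
    def crisp(cls, x: float) -> "TriangularFuzzyNumber":
        return cls(x, x, x)

    def scale(self, k: float) -> "TriangularFuzzyNumber":
        if k < 0:
            raise ValueError("negative scalar multiplication is not defined for TFNs")
        return TriangularFuzzyNumber(k * self.l, k * self.m, k * self.u)

    def add(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l + other.l, self.m + other.m, self.u + other.u)

    def astuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)


TFN = TriangularFuzzyNumber

YES_TOKENS = {"yes", "y", "true", "1"}
NO_TOKENS = {"no", "n", "false", "0"}


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered 7-term scale; each term owns a TFN on a common support."""

    name: str
    terms: tuple[str, ...]
    tfns: tuple[TriangularFuzzyNumber, ...]

    def __post_init__(self) -> None:
        if len(self.terms) != 7 or len(self.tfns) != 7:
            raise ValueError("a linguistic scale has exactly 7 terms")
        modes = [t.m for t in self.tfns]
        if any(b <= a for a, b in zip(modes, modes[1:])):
            raise ValueError("modal points must be strictly increasing")

    def encode(self, term: str) -> TriangularFuzzyNumber:
        key = term.strip().lower()
        for t, tfn in zip(self.terms, self.tfns):
            if t.lower() == key:
                return tfn
        raise EncodingError(
            f"unknown linguistic term {term!r}; scale {self.name!r} accepts {list(self.terms)}"
        )

    def term_index(self, term: str) -> int:
        key = term.strip().lower()
        return [t.lower() for t in self.terms].index(key)


def _default7() -> LinguisticScale:
    # term k (1..7) -> ((k-2)/6 clipped at 0, (k-1)/6, k/6 clipped at 1)
    terms = ("very low", "low", "medium low", "medium", "medium high", "high", "very high")
    tfns = tuple(
        TriangularFuzzyNumber(max((k - 2) / 6, 0.0), (k - 1) / 6, min(k / 6, 1.0))
        for k in range(1, 8)
    )
    return LinguisticScale("default7", terms, tfns)


_BUILTIN_SCALES = {"default7": _default7()}


def get_scale(name: str = "default7") -> LinguisticScale:
    try:
        return _BUILTIN_SCALES[name]
    except KeyError:
        raise EncodingError(
            f"unknown scale {name!r}; built-ins: {sorted(_BUILTIN_SCALES)}"
        ) from None


def load_scale(path: str | Path, name: str | None = None) -> LinguisticScale:
    """Read a scale from a CSV with columns term, l, m, u (7 rows)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"term", "l", "m", "u"}
    if not required.issubset(df.columns):
        raise EncodingError(f"scale file {path} must have columns {sorted(required)}")
    tfns = tuple(
        TriangularFuzzyNumber(float(r.l), float(r.m), float(r.u)) for r in df.itertuples()
    )
    return LinguisticScale(name or Path(path).stem, tuple(df["term"].astype(str)), tfns)


def encode_score(
    cell: object,
    kind: Literal["numeric", "binary", "linguistic"],
    scale: LinguisticScale | None = None,
) -> TriangularFuzzyNumber:
    """Fuzzify one raw evidence cell according to its column's data kind."""
    if kind == "numeric":
        try:
            return TFN.crisp(float(cell))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise EncodingError(f"non-numeric value {cell!r} in a numeric cell") from None
    if kind == "binary":
        token = str(cell).strip().lower()
        if token in YES_TOKENS:
            return TFN.crisp(1.0)
        if token in NO_TOKENS:
            return TFN.crisp(0.0)
        raise EncodingError(f"binary cell must be yes/no, got {cell!r}")
    if kind == "linguistic":
        if scale is None:
            scale = get_scale()
        return scale.encode(str(cell))
    raise EncodingError(f"unknown data kind {kind!r}")


def vertex_distance(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> float:
    """Vertex metric: sqrt(((dl)^2 + (dm)^2 + (du)^2) / 3).

    Coincides with |a - b| on degenerate (crisp) TFNs.
    """
    return math.sqrt(((a.l - b.l) ** 2 + (a.m - b.m) ** 2 + (a.u - b.u) ** 2) / 3.0)


def defuzzify(
    a: TriangularFuzzyNumber, method: Literal["graded_mean", "centroid"] = "graded_mean"
) -> float:
    """Crisp representative: centroid (l+m+u)/3 or graded mean (l+4m+u)/6."""
    if method == "centroid":
        return (a.l + a.m + a.u) / 3.0
    if method == "graded_mean":
        return (a.l + 4.0 * a.m + a.u) / 6.0
    raise EncodingError(f"unknown defuzzification method {method!r}")


def tfn_scale(a: TriangularFuzzyNumber, k: float) -> TriangularFuzzyNumber:
    return a.scale(k)


def tfn_add(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> TriangularFuzzyNumber:
    return a.add(b)
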