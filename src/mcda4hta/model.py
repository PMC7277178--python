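"""Model/Results layer: the end-to-end MCDA pipeline as fit-able objects.

``MCDADecisionModel`` binds the three inputs of the decision problem — the
criteria hierarchy, the panel's pairwise judgments (or pre-computed
weights), and the evidence table — and ``fit()`` executes
weights -> fuzzify -> normalize -> rank, returning an ``MCDAResults``
object that carries the global weights, per-matrix consistency ratios,
the per-method rankings, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ahp import (
    JudgmentSet,
    WeightVector,
    derive_local_weights,
    synthesize_global_weights,
)
from .errors import ConfigError, MCDAError
from .fuzzy import LinguisticScale, get_scale, load_scale
from .hierarchy import CriteriaHierarchy, load_hierarchy, plan_elicitation
from .performance import (
    FuzzyDecisionMatrix,
    PerformanceTable,
    fuzzify_table,
    load_table,
    normalize_matrix,
)
from .ranking import (
    RankingResult,
    rank_fuzzy_topsis,
    rank_fuzzy_vikor,
    rank_goal_programming,
)

logger = logging.getLogger(__name__)

METHOD_ALIASES = {
    "topsis": "fuzzy_topsis",
    "vikor": "fuzzy_vikor",
    "gp": "goal_programming",
    "fuzzy_topsis": "fuzzy_topsis",
    "fuzzy_vikor": "fuzzy_vikor",
    "goal_programming": "goal_programming",
}
ALL_METHODS = ("fuzzy_topsis", "fuzzy_vikor", "goal_programming")


@dataclass
class RunConfig:
    """Echo-able configuration of one pipeline run; no silent defaults."""

    methods: tuple[str, ...] = ALL_METHODS
    vikor_v: float = 0.5
    defuzz: Literal["graded_mean", "centroid"] = "graded_mean"
    scale_name: str = "default7"
    strict_cr: bool = False
    aggregation: Literal["judgments", "priorities"] = "judgments"
    eigen_method: Literal["eigenvector", "geometric_mean"] = "eigenvector"
    vikor_fuzzy_arithmetic: bool = False

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("no ranking method requested")
        try:
            self.methods = tuple(METHOD_ALIASES[m] for m in self.methods)
        except KeyError as exc:
            raise ConfigError(f"unknown method {exc}") from None
        if not (0.0 <= self.vikor_v <= 1.0):
            raise ConfigError(f"vikor_v must lie in [0, 1], got {self.vikor_v}")

    def echo(self) -> dict[str, object]:
        return {
            "methods": ",".join(self.methods),
            "vikor_v": self.vikor_v,
            "defuzz": self.defuzz,
            "scale": self.scale_name,
            "strict_cr": self.strict_cr,
            "aggregation": self.aggregation,
            "eigen_method": self.eigen_method,
            "vikor_fuzzy_arithmetic": self.vikor_fuzzy_arithmetic,
        }


class MCDADecisionModel:
    """The decision problem: hierarchy + panel judgments + evidence table.

    Exactly one of ``judgments`` / ``global_weights`` supplies the weight
    side of the problem.
    """

    def __init__(
        self,
        hierarchy: CriteriaHierarchy,
        performance: PerformanceTable,
        *,
        judgments: Sequence[JudgmentSet] | None = None,
        global_weights: WeightVector | None = None,
        scale: LinguisticScale | None = None,
    ) -> None:
        if (judgments is None) == (global_weights is None):
            raise ConfigError("provide exactly one of judgments or global_weights")
        self.hierarchy = hierarchy
        self.performance = performance
        self.judgments = list(judgments) if judgments else None
        self.global_weights = global_weights
        self.scale = scale or get_scale()

    @classmethod
    def from_files(
        cls,
        hierarchy_path: str | Path,
        table_path: str | Path,
        *,
        responses_path: str | Path | None = None,
        weights_path: str | Path | None = None,
        scale: str | Path | None = None,
    ) -> "MCDADecisionModel":
        from .io import load_global_weights, load_responses

        h = load_hierarchy(hierarchy_path)
        table = load_table(table_path, h)
        judgments = global_w = None
        if responses_path is not None:
            judgments = load_responses(responses_path, plan_elicitation(h))
        if weights_path is not None:
            global_w = load_global_weights(weights_path)
        scale_obj = None
        if scale is not None:
            p = Path(str(scale))
            scale_obj = load_scale(p) if p.exists() else get_scale(str(scale))
        return cls(h, table, judgments=judgments, global_weights=global_w, scale=scale_obj)

    def fit(self, config: RunConfig | None = None, **kwargs) -> "MCDAResults":
        """Run the pipeline and return results; keyword args override config."""
        if config is not None and kwargs:
            raise ConfigError("pass either a RunConfig or keyword overrides, not both")
        cfg = config if config is not None else RunConfig(**kwargs)
        local_weights: dict[str, WeightVector] = {}
        crs: dict[str, float] = {}
        if self.judgments is not None:
            local_weights, crs = derive_local_weights(
                self.hierarchy,
                self.judgments,
                aggregation=cfg.aggregation,
                eigen_method=cfg.eigen_method,
                strict_cr=cfg.strict_cr,
            )
            global_w = synthesize_global_weights(self.hierarchy, local_weights)
        else:
            global_w = self.global_weights
            assert global_w is not None
        fuzzy = fuzzify_table(self.performance, global_w.weights, self.scale)
        normalized = normalize_matrix(fuzzy)
        rankings: dict[str, RankingResult] = {}
        for method in cfg.methods:
            if method == "fuzzy_topsis":
                rankings[method] = rank_fuzzy_topsis(normalized)
            elif method == "fuzzy_vikor":
                rankings[method] = rank_fuzzy_vikor(
                    normalized,
                    cfg.vikor_v,
                    defuzz=cfg.defuzz,
                    fuzzy_arithmetic=cfg.vikor_fuzzy_arithmetic,
                )
            else:
                rankings[method] = rank_goal_programming(normalized, defuzz=cfg.defuzz)
        return MCDAResults(
            model=self,
            config=cfg,
            local_weights=local_weights,
            global_weights=global_w,
            consistency=crs,
            matrix=normalized,
            rankings=rankings,
        )


@dataclass
class MCDAResults:
    """Fitted decision results: weights, diagnostics, per-method rankings."""

    model: MCDADecisionModel
    config: RunConfig
    local_weights: Mapping[str, WeightVector]
    global_weights: WeightVector
    consistency: Mapping[str, float]
    matrix: FuzzyDecisionMatrix
    rankings: Mapping[str, RankingResult]

    @property
    def alternatives(self) -> tuple[str, ...]:
        return self.matrix.alternatives

    def indices_frame(self) -> pd.DataFrame:
        """Alternatives x methods table of indices (lower = better)."""
        data = {
            method: [r.indices[a] for a in self.alternatives]
            for method, r in self.rankings.items()
        }
        return pd.DataFrame(data, index=list(self.alternatives))

    def winners(self) -> dict[str, str]:
        return {method: r.best for method, r in self.rankings.items()}

    def high_cr_matrices(self, threshold: float = 0.1) -> dict[str, float]:
        return {m: c for m, c in self.consistency.items() if c > threshold}

    def summary(self) -> str:
        """Human-readable report: config echo, rankings, diagnostics."""
        lines = [
            f"MCDA decision report (mcda4hta {__version__})",
            "=" * 46,
            f"goal: {self.model.hierarchy.goal}",
            f"alternatives: {', '.join(self.alternatives)}",
            f"criteria used: {len(self.matrix.columns)}"
            + (f" (dropped: {', '.join(self.matrix.dropped_columns)})"
               if self.matrix.dropped_columns else ""),
            "",
            "configuration (all values explicit):",
        ]
        for k, v in self.config.echo().items():
            lines.append(f"  {k} = {v}")
        lines.append("")
        lines.append("indices (lower = better):")
        df = self.indices_frame().round(3)
        lines.append(df.to_string())
        lines.append("")
        for method, result in self.rankings.items():
            lines.append(f"{method}: best = {result.best}")
        if self.consistency:
            high = self.high_cr_matrices()
            lines.append("")
            lines.append(
                f"consistency: {len(self.consistency)} matrices, "
                f"{len(high)} with CR > 0.1"
                + (f" ({', '.join(f'{m}:{c:.3f}' for m, c in sorted(high.items()))})"
                   if high else "")
            )
        if self.matrix.dropped_columns:
            lines.append(
                "dropped columns (missing evidence for >=1 alternative): "
                + ", ".join(self.matrix.dropped_columns)
            )
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str | Path) -> list[Path]:
        """Write one CSV per method plus the combined summary; deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for method, result in self.rankings.items():
            df = result.to_frame()
            df["index"] = df["index"].map(lambda x: f"{x:.6f}")
            extra = {}
            if method == "fuzzy_topsis":
                extra = {"d_plus": result.intermediates["d_plus"],
                         "d_minus": result.intermediates["d_minus"]}
            elif method == "fuzzy_vikor":
                extra = {"S": result.intermediates["S"], "R": result.intermediates["R"]}
            for name, mapping in extra.items():
                df[name] = [f"{mapping[a]:.6f}" for a in df["alternative"]]
            path = out / f"{method}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        path = out / "summary.md"
        path.write_text(self.summary())
        written.append(path)
        return written


def run_pipeline(
    hierarchy_path: str | Path,
    table_path: str | Path,
    *,
    responses_path: str | Path | None = None,
    weights_path: str | Path | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> MCDAResults:
    """File-level convenience wrapper: load, fit, optionally write a report."""
    model = MCDADecisionModel.from_files(
        hierarchy_path,
        table_path,
        responses_path=responses_path,
        weights_path=weights_path,
    )
    results = model.fit(config or RunConfig())
    if out_dir is not None:
        results.save(out_dir)
    return results
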