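"""Weighted multi-objective scoring and selection of feedback loops.

Each loop i is scored under a weighting scenario j as

    S_ij = (w1j/2) <ND>_i / max(ND) + (w1j/2) <BC>_i / max(BC)
         + w2j <DP>_i / max(DP) + w3j <GP>_i / max(GP)
         + w4j <|FC|>_i / max(|FC|)

where <ND> and <BC> are the mean node degree and betweenness over the loop's
members, <DP> the count of members in the disease pathway, <GP> the mean
random-walk prioritization score and <|FC|> the mean absolute log2
fold-change.  Maxima run over all loops under consideration, so each term is
normalized to [0, 1]; the topology weight w1 is split evenly between degree
and betweenness so structure is not over-emphasized.  The top k loops per
scenario are pooled into a non-redundant union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .loops import FeedbackLoop
from .network import NodeMetrics
from .scoring import ExpressionContrast, PathwayFlags, PrioritizationScore

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class WeightingScenario:
    """One weight vector (w1..w4) of the multi-objective function.

    Weights must be non-negative and sum to 1 (within 1e-9); the degenerate
    all-zero vector is also accepted and scores every loop 0.
    """

    id: int
    w1: float
    w2: float
    w3: float
    w4: float

    def __post_init__(self) -> None:
        weights = (self.w1, self.w2, self.w3, self.w4)
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        total = sum(weights)
        if abs(total - 1.0) > _WEIGHT_TOL and total > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 (or all be 0), got {total}")


def default_scenarios() -> list[WeightingScenario]:
    """13 scenarios spanning the Pareto directions of the four criteria:
    the 4 one-hot vectors, the 6 equal-weight pairs, the uniform vector, and
    two mixed emphases (topology-leaning and fold-change-leaning)."""
    vectors: list[tuple[float, float, float, float]] = []
    for i in range(4):
        v = [0.0] * 4
        v[i] = 1.0
        vectors.append(tuple(v))
    for i in range(4):
        for j in range(i + 1, 4):
            v = [0.0] * 4
            v[i] = v[j] = 0.5
            vectors.append(tuple(v))
    vectors.append((0.25, 0.25, 0.25, 0.25))
    vectors.append((0.4, 0.2, 0.2, 0.2))
    vectors.append((0.2, 0.2, 0.2, 0.4))
    return [WeightingScenario(j + 1, *v) for j, v in enumerate(vectors)]


def load_scenarios(path: str | Path) -> list[WeightingScenario]:
    """Scenario config: YAML/JSON list of 4-weight vectors."""
    raw = yaml.safe_load(Path(path).read_text())
    return [WeightingScenario(j + 1, *map(float, v)) for j, v in enumerate(raw)]


@dataclass(frozen=True)
class MotifFeatures:
    """The five raw per-loop criteria entering the score."""

    nd: float
    bc: float
    dp: float
    gp: float
    abs_fc: float


@dataclass(frozen=True)
class MotifScore:
    motif_key: str
    scenario_id: int
    score: float
    components: tuple[float, float, float, float, float]  # normalized terms
    features: MotifFeatures


def motif_features(
    loop: FeedbackLoop,
    metrics: NodeMetrics,
    flags: PathwayFlags,
    gp: PrioritizationScore,
    fc: ExpressionContrast,
) -> MotifFeatures:
    """Means of ND/BC/GP/|FC| and the DP member count over the loop's nodes."""
    for node in loop.nodes:
        if node not in metrics.degree or node not in metrics.betweenness:
            raise KeyError(f"node {node!r} missing from node metrics")
        if node not in flags.in_disease_pathway:
            raise KeyError(f"node {node!r} missing from pathway flags")
        if node not in gp.gp:
            raise KeyError(f"node {node!r} missing from prioritization scores")
    n = len(loop.nodes)
    return MotifFeatures(
        nd=sum(metrics.degree[v] for v in loop.nodes) / n,
        bc=sum(metrics.betweenness[v] for v in loop.nodes) / n,
        dp=float(sum(flags[v] for v in loop.nodes)),
        gp=sum(gp[v] for v in loop.nodes) / n,
        abs_fc=sum(fc.abs_fc_for(v) for v in loop.nodes) / n,
    )


def score_motifs(
    features: dict[str, MotifFeatures], scenario: WeightingScenario
) -> list[MotifScore]:
    """Score every loop under one scenario.

    A criterion whose maximum over all loops is 0 contributes 0 for every
    loop (the normalization is undefined and the criterion carries no
    information).  Results are sorted by the deterministic ranking order.
    """
    if not features:
        raise ValueError("no loop features to score")
    max_nd = max(f.nd for f in features.values())
    max_bc = max(f.bc for f in features.values())
    max_dp = max(f.dp for f in features.values())
    max_gp = max(f.gp for f in features.values())
    max_fc = max(f.abs_fc for f in features.values())

    def norm(value: float, maximum: float) -> float:
        return value / maximum if maximum > 0 else 0.0

    scores = []
    for key, f in features.items():
        terms = (
            norm(f.nd, max_nd),
            norm(f.bc, max_bc),
            norm(f.dp, max_dp),
            norm(f.gp, max_gp),
            norm(f.abs_fc, max_fc),
        )
        s = (
            scenario.w1 / 2 * terms[0]
            + scenario.w1 / 2 * terms[1]
            + scenario.w2 * terms[2]
            + scenario.w3 * terms[3]
            + scenario.w4 * terms[4]
        )
        scores.append(MotifScore(key, scenario.id, s, terms, f))
    scores.sort(key=_rank_key)
    return scores


def _rank_key(ms: MotifScore) -> tuple:
    # score desc, then |FC| desc (the most context-specific criterion), then key asc
    return (-ms.score, -ms.features.abs_fc, ms.motif_key)


def rank_and_select(
    scores_by_scenario: dict[int, list[MotifScore]], k: int = 10
) -> list[str]:
    """Top-k loops per scenario, pooled into a sorted non-redundant union.

    Ties break by score descending, |FC| descending, canonical key ascending,
    so the selection is identical across runs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: set[str] = set()
    for scenario_id in sorted(scores_by_scenario):
        ranked = sorted(scores_by_scenario[scenario_id], key=_rank_key)
        selected.update(ms.motif_key for ms in ranked[:k])
    return sorted(selected)


def write_scores(scores: list[MotifScore], path: str | Path) -> None:
    lines = ["motif_key\tscenario\tscore\tnd\tbc\tdp\tgp\tabs_fc"]
    for ms in scores:
        f = ms.features
        lines.append(
            f"{ms.motif_key}\t{ms.scenario_id}\t{ms.score:.6g}"
            f"\t{f.nd:.6g}\t{f.bc:.6g}\t{f.dp:.6g}\t{f.gp:.6g}\t{f.abs_fc:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def validate_score_bounds(scores: list[MotifScore]) -> None:
    """Sanity check: with weights summing to 1 every score lies in [0, 1]."""
    for ms in scores:
        if not (-_WEIGHT_TOL <= ms.score <= 1 + _WEIGHT_TOL) or math.isnan(ms.score):
            raise AssertionError(f"score out of bounds: {ms}")
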