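"""Enumeration and sign classification of signed feedback loops.

A feedback loop is a simple directed cycle.  Its sign follows the standard
product rule: positive with an even number of inhibitory edges, negative with
an odd number, and neutral as soon as any edge has an unknown effect.  Loops
are deduplicated by a rotation-invariant canonical key so that every cycle is
reported exactly once, in a deterministic order.  Parallel edges carrying
conflicting signs between the same node pair give rise to distinct loops, one
per sign combination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .network import Effect, Interaction, RegulatoryNetwork

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"
SIGN_NEUTRAL = "neutral"


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with signed edges.

    ``nodes`` stores the cycle in canonical rotation (lexicographically
    smallest start node); ``edges[i]`` runs from ``nodes[i]`` to
    ``nodes[(i + 1) % len]``.
    """

    nodes: tuple[str, ...]
    edges: tuple[Interaction, ...]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if n == 0 or len(self.edges) != n:
            raise ValueError("a loop needs one edge per node")
        if len(set(self.nodes)) != n:
            raise ValueError("loop nodes must be distinct (simple cycle)")
        for i, edge in enumerate(self.edges):
            if edge.source != self.nodes[i] or edge.target != self.nodes[(i + 1) % n]:
                raise ValueError("edges do not form a closed cycle over the node order")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def sign(self) -> str:
        return classify_loop_sign(self)

    @property
    def canonical_key(self) -> str:
        effects = ",".join(e.effect.value for e in self.edges)
        return "|".join(self.nodes) + ";" + effects

    @staticmethod
    def from_cycle(nodes: list[str], edges: list[Interaction]) -> "FeedbackLoop":
        """Canonicalize a cycle given in arbitrary rotation."""
        n = len(nodes)
        shift = min(range(n), key=lambda i: nodes[i])
        return FeedbackLoop(
            nodes=tuple(nodes[(shift + i) % n] for i in range(n)),
            edges=tuple(edges[(shift + i) % n] for i in range(n)),
        )


def classify_loop_sign(loop: FeedbackLoop) -> str:
    """Sign class by the parity/product rule; unknown effects dominate."""
    if any(e.effect is Effect.UNKNOWN for e in loop.edges):
        return SIGN_NEUTRAL
    inhibitions = sum(e.effect is Effect.INHIBITION for e in loop.edges)
    return SIGN_NEGATIVE if inhibitions % 2 else SIGN_POSITIVE


def enumerate_feedback_loops(
    net: RegulatoryNetwork, max_length: int = 3
) -> list[FeedbackLoop]:
    """All simple directed cycles of length <= ``max_length``, each once.

    Cycles are found on the simple digraph and then expanded over every
    combination of parallel edge effects.  Output is sorted by canonical key.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    g = net.to_digraph()
    loops: dict[str, FeedbackLoop] = {}
    for cycle in nx.simple_cycles(g, length_bound=max_length):
        n = len(cycle)
        per_edge_effects = [
            g[cycle[i]][cycle[(i + 1) % n]]["effects"] for i in range(n)
        ]
        for combo in itertools.product(*per_edge_effects):
            edges = [
                Interaction(cycle[i], cycle[(i + 1) % n], combo[i]) for i in range(n)
            ]
            loop = FeedbackLoop.from_cycle(list(cycle), edges)
            loops[loop.canonical_key] = loop
    return [loops[k] for k in sorted(loops)]


def filter_loops(
    loops: list[FeedbackLoop], min_length: int = 2, max_length: int | None = None
) -> list[FeedbackLoop]:
    """Length filter; by default drops self-loops, which are enumerated but
    excluded from ranking."""
    return [
        lp
        for lp in loops
        if len(lp) >= min_length and (max_length is None or len(lp) <= max_length)
    ]


def sign_census(loops: list[FeedbackLoop]) -> dict[str, int]:
    census = {SIGN_POSITIVE: 0, SIGN_NEGATIVE: 0, SIGN_NEUTRAL: 0}
    for loop in loops:
        census[loop.sign] += 1
    return census


def write_loops(loops: list[FeedbackLoop], path: str | Path) -> None:
    """Export loops as TSV: canonical_key, length, sign, node list, edge effects."""
    lines = ["canonical_key\tlength\tsign\tnodes\teffects"]
    for loop in loops:
        lines.append(
            "\t".join(
                [
                    loop.canonical_key,
                    str(len(loop)),
                    loop.sign,
                    ",".join(loop.nodes),
                    ",".join(e.effect.value for e in loop.edges),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
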