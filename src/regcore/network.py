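"""Signed directed regulatory networks: loading, validation, topology metrics.

A regulatory network is a directed multigraph whose edges carry a regulatory
effect (activation, inhibition, or unknown).  Two edges between the same pair
of nodes with *different* effects coexist; an exact duplicate triple
``(source, target, effect)`` is collapsed with a warning.  Node identifiers
are case-sensitive gene symbols; no identifier mapping is attempted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NODE_CATEGORIES = frozenset(
    {"gene", "protein", "miRNA", "complex", "receptor", "ligand", "phenotype", "other"}
)


class Effect(str, enum.Enum):
    """Regulatory effect of an interaction."""

    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    UNKNOWN = "unknown"


#: tolerant SIF relation vocabulary -> effect
_RELATION_VOCAB = {
    "activates": Effect.ACTIVATION,
    "activation": Effect.ACTIVATION,
    "->": Effect.ACTIVATION,
    "inhibits": Effect.INHIBITION,
    "inhibition": Effect.INHIBITION,
    "-|": Effect.INHIBITION,
    "unknown": Effect.UNKNOWN,
}


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


@dataclass(frozen=True)
class Interaction:
    """A signed directed interaction between two molecular entities."""

    source: str
    target: str
    effect: Effect
    provenance: str | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("interaction endpoints must be non-empty strings")
        if not isinstance(self.effect, Effect):
            object.__setattr__(self, "effect", Effect(self.effect))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.effect.value)


class RegulatoryNetwork:
    """A validated signed directed regulatory network with node categories."""

    def __init__(self) -> None:
        self._categories: dict[str, str] = {}
        self._interactions: dict[tuple[str, str, str], Interaction] = {}

    # -- construction -------------------------------------------------------
    def add_node(self, node: str, category: str = "other") -> None:
        if not node:
            raise ValueError("node identifier must be a non-empty string")
        if category not in NODE_CATEGORIES:
            raise ValueError(f"unknown node category {category!r}")
        self._categories[node] = category

    def add_interaction(self, interaction: Interaction, warn_duplicates: bool = True) -> bool:
        """Add an interaction, registering endpoints.  Returns False on duplicate."""
        if interaction.key in self._interactions:
            if warn_duplicates:
                logger.warning("duplicate interaction collapsed: %s", interaction.key)
            return False
        for endpoint in (interaction.source, interaction.target):
            self._categories.setdefault(endpoint, "other")
        self._interactions[interaction.key] = interaction
        return True

    # -- accessors ----------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._categories))

    @property
    def interactions(self) -> tuple[Interaction, ...]:
        return tuple(self._interactions[k] for k in sorted(self._interactions))

    @property
    def categories(self) -> Mapping[str, str]:
        return dict(self._categories)

    def category(self, node: str) -> str:
        return self._categories[node]

    def __contains__(self, node: str) -> bool:
        return node in self._categories

    def __len__(self) -> int:
        return len(self._categories)

    @property
    def n_interactions(self) -> int:
        return len(self._interactions)

    # -- graph views --------------------------------------------------------
    def to_multidigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for ia in self.interactions:
            g.add_edge(ia.source, ia.target, effect=ia.effect)
        return g

    def to_digraph(self) -> nx.DiGraph:
        """Simple digraph view; parallel effects merged per (source, target)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for ia in self.interactions:
            if g.has_edge(ia.source, ia.target):
                g[ia.source][ia.target]["effects"].append(ia.effect)
            else:
                g.add_edge(ia.source, ia.target, effects=[ia.effect])
        return g

    def undirected_skeleton(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for ia in self.interactions:
            g.add_edge(ia.source, ia.target)
        return g

    # -- IO -----------------------------------------------------------------
    def write(self, path: str | Path, dialect: str = "sif") -> None:
        path = Path(path)
        lines: list[str] = []
        if dialect == "sif":
            relation = {
                Effect.ACTIVATION: "activates",
                Effect.INHIBITION: "inhibits",
                Effect.UNKNOWN: "unknown",
            }
            for ia in self.interactions:
                lines.append(f"{ia.source}\t{relation[ia.effect]}\t{ia.target}")
        elif dialect == "edge_table":
            lines.append("source\ttarget\teffect\tprovenance")
            for ia in self.interactions:
                lines.append(
                    f"{ia.source}\t{ia.target}\t{ia.effect.value}\t{ia.provenance or ''}"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        path.write_text("\n".join(lines) + "\n")


def load_network(path: str | Path, dialect: str = "sif") -> RegulatoryNetwork:
    """Load a network from a SIF or extended edge-table file.

    SIF lines read ``source <tab> relation <tab> target``; relations outside
    the tolerant vocabulary map to :attr:`Effect.UNKNOWN` with a warning.  The
    edge-table dialect requires columns source/target/effect(/provenance) and
    rejects unknown effect tokens, naming the offending line.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:  # unreadable file -> I/O error
        raise IOError(f"cannot read network file {path}: {exc}") from exc

    net = RegulatoryNetwork()
    lines = text.splitlines()
    if dialect == "sif":
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise NetworkParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            source, relation, target = parts[0], parts[1], parts[2]
            effect = _RELATION_VOCAB.get(relation.lower())
            if effect is None:
                logger.warning(
                    "%s:%d: unrecognized relation %r mapped to unknown", path, lineno, relation
                )
                effect = Effect.UNKNOWN
            net.add_interaction(Interaction(source, target, effect))
    elif dialect == "edge_table":
        body = [(i, ln) for i, ln in enumerate(lines, start=1) if ln.strip() and not ln.startswith("#")]
        if body and body[0][1].lower().startswith("source"):
            body = body[1:]
        for lineno, raw in body:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise NetworkParseError(f"{path}:{lineno}: expected >=3 fields, got {len(parts)}")
            source, target, token = parts[0].strip(), parts[1].strip(), parts[2].strip()
            effect = _RELATION_VOCAB.get(token.lower())
            if effect is None:
                raise NetworkParseError(f"{path}:{lineno}: unknown effect token {token!r}")
            provenance = parts[3].strip() or None if len(parts) > 3 else None
            net.add_interaction(Interaction(source, target, effect, provenance))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if net.n_interactions == 0:
        raise NetworkParseError(f"{path}: no interactions")
    return net


# ---------------------------------------------------------------------------
# topology metrics
# ---------------------------------------------------------------------------

@dataclass
class NodeMetrics:
    """Per-node degree (in + out, counting multiplicity) and directed betweenness.

    Betweenness is unnormalized (raw shortest-path counts); any normalization
    happens downstream, where motif scores divide by the maximum over motifs.
    """

    degree: dict[str, int] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)


def compute_node_metrics(net: RegulatoryNetwork) -> NodeMetrics:
    if len(net) == 0:
        raise ValueError("empty network")
    multi = net.to_multidigraph()
    degree = {n: d for n, d in multi.degree()}
    betweenness = nx.betweenness_centrality(net.to_digraph(), normalized=False)
    return NodeMetrics(degree=degree, betweenness=dict(betweenness))


@dataclass
class GlobalStats:
    """Whole-network summary statistics.

    Distance-based statistics (diameter, radius, characteristic path length)
    are computed over directed *reachable* ordered pairs only; on graphs that
    are not strongly connected this convention is flagged via
    ``strongly_connected``.
    """

    node_count: int
    edge_count: int
    clustering_coefficient: float
    diameter: int
    radius: int
    characteristic_path_length: float
    average_neighbors: float
    strongly_connected: bool


def network_summary(net: RegulatoryNetwork) -> GlobalStats:
    if len(net) == 0:
        raise ValueError("empty network")
    g = net.to_digraph()
    skeleton = net.undirected_skeleton()
    skeleton_simple = nx.Graph(skeleton)
    skeleton_simple.remove_edges_from(nx.selfloop_edges(skeleton_simple))

    distances: list[int] = []
    eccentricities: list[int] = []
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        reach = [d for t, d in lengths.items() if t != source]
        distances.extend(reach)
        if reach:
            eccentricities.append(max(reach))
    diameter = max(distances) if distances else 0
    radius = min(eccentricities) if eccentricities else 0
    cpl = sum(distances) / len(distances) if distances else 0.0

    n = len(net)
    return GlobalStats(
        node_count=n,
        edge_count=net.n_interactions,
        clustering_coefficient=nx.average_clustering(skeleton_simple) if n else 0.0,
        diameter=diameter,
        radius=radius,
        characteristic_path_length=cpl,
        average_neighbors=sum(dict(skeleton_simple.degree()).values()) / n,
        strongly_connected=nx.is_strongly_connected(g) if n else False,
    )


def network_from_interactions(
    interactions: Iterable[Interaction],
    categories: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Build a network from an interaction iterable (duplicates collapsed silently)."""
    net = RegulatoryNetwork()
    for ia in interactions:
        net.add_interaction(ia, warn_duplicates=False)
    if categories:
        for node, cat in categories.items():
            if node in net:
                net.add_node(node, cat)
    return net
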