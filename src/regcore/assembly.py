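"""Assembly of a regulatory core from selected feedback loops.

Top-ranked loops are merged into one network (set union of their nodes and
edges).  When the merge leaves disjoint sub-networks, they are reconnected
with *direct interactions* taken verbatim from the full network: every full
network edge whose endpoints lie in different weak components is added and
labeled as a bridge.  Optionally, component pairs that no direct edge links
can be joined through shortest two-step paths, importing the intermediate
node.  The core is therefore always a subgraph of (full network union
selected loops); no edge is invented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .loops import FeedbackLoop
from .network import Interaction, RegulatoryNetwork, network_from_interactions


@dataclass
class RegulatoryCore:
    network: RegulatoryNetwork
    bridge_edges: tuple[Interaction, ...]
    component_labels: dict[str, int]


def merge_motifs(
    selected: Iterable[FeedbackLoop],
    categories: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Union of the selected loops' nodes and edges, deduplicated.

    Phenotype-category nodes (and their loop edges) are excluded: the
    phenotype enters the logic model through its own output layer, not the
    regulatory core.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("at least one motif is required")
    categories = categories or {}

    def is_phenotype(node: str) -> bool:
        return categories.get(node) == "phenotype"

    interactions = [
        edge
        for loop in selected
        for edge in loop.edges
        if not (is_phenotype(edge.source) or is_phenotype(edge.target))
    ]
    net = network_from_interactions(interactions, categories)
    for loop in selected:
        for node in loop.nodes:
            if not is_phenotype(node) and node not in net:
                net.add_node(node, categories.get(node, "other"))
    return net


def connect_components(
    core: RegulatoryNetwork,
    full: RegulatoryNetwork,
    allow_two_step: bool = False,
) -> RegulatoryCore:
    """Reconnect disjoint sub-networks of the core with full-network edges.

    All direct inter-component edges of the full network are added as
    bridges (no minimality is attempted: every true edge enriches the
    downstream logic model).  With ``allow_two_step`` enabled, component
    pairs left unlinked are joined by length-2 full-network paths, importing
    the intermediate node.  Idempotent: a second run adds nothing.
    """
    for node in core.nodes:
        if node not in full:
            raise KeyError(f"core node {node!r} absent from the full network")

    merged = network_from_interactions(core.interactions, core.categories)
    for node in core.nodes:
        if node not in merged:
            merged.add_node(node, core.category(node))

    components = _weak_components(merged)
    labels = {
        node: idx for idx, comp in enumerate(components) for node in comp
    }

    bridges: list[Interaction] = []
    if len(components) > 1:
        for ia in full.interactions:
            if ia.source in labels and ia.target in labels and labels[ia.source] != labels[ia.target]:
                if merged.add_interaction(ia, warn_duplicates=False):
                    bridges.append(ia)

    if allow_two_step:
        bridges.extend(_two_step_bridges(merged, full))

    return RegulatoryCore(
        network=merged,
        bridge_edges=tuple(bridges),
        component_labels=labels,
    )


def _weak_components(net: RegulatoryNetwork) -> list[list[str]]:
    g = net.to_digraph()
    comps = [sorted(c) for c in nx.weakly_connected_components(g)]
    comps.sort()  # deterministic component ids
    return comps


def _two_step_bridges(
    merged: RegulatoryNetwork, full: RegulatoryNetwork
) -> list[Interaction]:
    """Join still-disjoint component pairs via one intermediate full-network
    node (length-2 undirected paths; edge orientation is irrelevant for weak
    connectivity).  Iterates until no pair of components sits within two
    hops of each other in the full network's skeleton."""
    added: list[Interaction] = []
    incident: dict[str, list[Interaction]] = {}
    for ia in full.interactions:
        incident.setdefault(ia.source, []).append(ia)
        if ia.target != ia.source:
            incident.setdefault(ia.target, []).append(ia)

    changed = True
    while changed:
        changed = False
        comps = _weak_components(merged)
        if len(comps) <= 1:
            break
        label = {n: i for i, c in enumerate(comps) for n in c}
        for u in merged.nodes:
            for first in incident.get(u, []):
                mid = first.target if first.source == u else first.source
                if mid in label and label[mid] == label[u]:
                    continue
                for second in incident.get(mid, []):
                    v = second.target if second.source == mid else second.source
                    if v in label and label[v] != label[u]:
                        for ia in (first, second):
                            if merged.add_interaction(ia, warn_duplicates=False):
                                added.append(ia)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
    return added


def write_core(core: RegulatoryCore, path: str | Path) -> None:
    """Edge table with a bridge flag column."""
    bridge_keys = {ia.key for ia in core.bridge_edges}
    lines = ["source\ttarget\teffect\tbridge"]
    for ia in core.network.interactions:
        lines.append(
            f"{ia.source}\t{ia.target}\t{ia.effect.value}\t{str(ia.key in bridge_keys).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_component_labels(core: RegulatoryCore, path: str | Path) -> None:
    lines = ["node\tcomponent"]
    for node in sorted(core.component_labels):
        lines.append(f"{node}\t{core.component_labels[node]}")
    Path(path).write_text("\n".join(lines) + "\n")
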