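"""Synthetic inputs with the statistical structure the workflow assumes, and
the packaged bladder/breast core logic models.

The generators are pure functions of a :class:`SyntheticSpec` (which carries
a mandatory seed), so every fixture used in tests and examples is
reproducible byte for byte.  Random signed digraphs stand in for a curated
interaction map; two-group log-normal expression tables with planted
log2 fold-changes stand in for an invasive vs non-invasive cell-line
contrast; the two packaged rule files encode the tumor-core logic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .logic import LogicModel, loads_model
from .network import Effect, Interaction, RegulatoryNetwork


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults mirror the workflow's assumed data: sparse signed digraphs with
    roughly balanced activation/inhibition and a small unknown fraction
    (matching the sign composition of curated cancer maps, where neutral
    loops are rare), and cell-line-like expression with log2-scale replicate
    noise of 0.25 and 20 samples per group.
    """

    n_nodes: int = 30
    edge_prob: float = 0.08
    inhibition_frac: float = 0.45
    unknown_frac: float = 0.01
    n_samples_per_group: int = 20
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_prob", "inhibition_frac", "unknown_frac"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.inhibition_frac + self.unknown_frac > 1:
            raise ValueError("inhibition_frac + unknown_frac must not exceed 1")
        if self.n_nodes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_nodes and n_samples_per_group must be positive")


def _node_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def random_signed_network(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Directed G(n, p) with independently drawn edge effects."""
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec.n_nodes)
    net = RegulatoryNetwork()
    for name in names:
        net.add_node(name, "gene")
    for source in names:
        for target in names:
            if source == target:
                continue
            if rng.random() < spec.edge_prob:
                u = rng.random()
                if u < spec.inhibition_frac:
                    effect = Effect.INHIBITION
                elif u < spec.inhibition_frac + spec.unknown_frac:
                    effect = Effect.UNKNOWN
                else:
                    effect = Effect.ACTIVATION
                net.add_interaction(Interaction(source, target, effect))
    return net


def synthetic_expression(
    spec: SyntheticSpec, genes: list[str] | None = None
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Two-group log-normal expression with planted fold-changes.

    Returns ``(table, invasive_samples, noninvasive_samples)``.  Baseline
    log2 abundances are gene-specific; genes named in
    ``spec.planted_log2fc`` are shifted by that amount in the invasive
    group, all other genes are null.
    """
    rng = np.random.default_rng(spec.seed)
    if genes is None:
        genes = _node_names(spec.n_nodes)
    n = spec.n_samples_per_group
    invasive = [f"inv{i + 1:02d}" for i in range(n)]
    noninvasive = [f"non{i + 1:02d}" for i in range(n)]
    baseline = rng.normal(6.0, 1.0, size=len(genes))
    data = np.empty((len(genes), 2 * n))
    for row, gene in enumerate(genes):
        shift = spec.planted_log2fc.get(gene, 0.0)
        log2_inv = baseline[row] + shift + rng.normal(0.0, spec.noise_sd, size=n)
        log2_non = baseline[row] + rng.normal(0.0, spec.noise_sd, size=n)
        data[row, :n] = 2.0 ** log2_inv
        data[row, n:] = 2.0 ** log2_non
    table = pd.DataFrame(data, index=pd.Index(genes, name="gene"),
                         columns=invasive + noninvasive)
    return table, invasive, noninvasive


def _packaged_model(filename: str) -> LogicModel:
    text = resources.files("regcore").joinpath("data", filename).read_text()
    return loads_model(text, name=filename.removesuffix(".txt"))


def bladder_core_model() -> LogicModel:
    """The packaged bladder core model: 6 inputs, hence a 64-vector sweep."""
    return _packaged_model("bladder_model.txt")


def breast_core_model() -> LogicModel:
    """The packaged breast core model: 7 inputs, hence a 128-vector sweep."""
    return _packaged_model("breast_model.txt")


def default_emt_markers() -> list[str]:
    """The packaged, editable EMT marker seed list."""
    text = resources.files("regcore").joinpath("data", "emt_markers.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
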