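"""Summaries of input-space sweeps: equivalence classes, driver signatures,
and random signature controls.

A full sweep over the 2^m input vectors usually shows that only a few inputs
matter: toggling the others never changes the phenotype.  Grouping vectors by
the states of the *influential* inputs collapses the sweep into equivalence
classes (the structure of the published outcome tables, where e.g. all eight
combinations of the three free receptors share one row).  The driver
signature is the influential input set together with the direction attaining
the maximal phenotype level.  Random signatures of matched size serve as
negative controls for downstream cohort validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .assembly import RegulatoryCore
from .logic import SimulationResult
from .network import RegulatoryNetwork


@dataclass(frozen=True)
class EquivalenceClass:
    fixed_states: tuple[tuple[str, int], ...]  # influential input -> state
    size: int
    phenotype: int | None
    phenotype_levels: tuple[int, ...] = ()


@dataclass
class EquivalenceClassTable:
    influential_inputs: tuple[str, ...]
    free_inputs: tuple[str, ...]
    classes: tuple[EquivalenceClass, ...]

    @property
    def total_size(self) -> int:
        return sum(c.size for c in self.classes)


@dataclass(frozen=True)
class DriverSignature:
    """Influential inputs with the direction attaining the maximal phenotype.

    ``tied`` carries every maximal class when the maximum is not unique.
    """

    inputs: tuple[str, ...]
    direction: tuple[str, ...]  # "high" / "low" per input
    level: int | None
    tied: tuple[EquivalenceClass, ...] = ()


def _outcome_key(res: SimulationResult) -> tuple:
    if res.is_fixed_point:
        return ("fixed", res.phenotype)
    return ("cycle", res.phenotype_levels)


def collapse_equivalence_classes(
    results: list[SimulationResult],
) -> EquivalenceClassTable:
    """Identify free inputs and group the sweep by the influential ones.

    An input is *free* iff toggling it never changes the outcome in any
    context (exact full-sweep comparison, not a sampled estimate).  Requires
    a complete sweep: exactly one result per input vector.
    """
    if not results:
        raise ValueError("empty sweep")
    inputs = tuple(results[0].input)
    m = len(inputs)
    by_vector = {tuple(r.input[i] for i in inputs): r for r in results}
    if len(by_vector) != 2 ** m or len(results) != 2 ** m:
        raise ValueError(
            f"incomplete sweep: expected {2 ** m} distinct input vectors, got {len(by_vector)}"
        )

    influential = []
    for idx, name in enumerate(inputs):
        for vector, res in by_vector.items():
            toggled = list(vector)
            toggled[idx] = 1 - toggled[idx]
            if _outcome_key(res) != _outcome_key(by_vector[tuple(toggled)]):
                influential.append(name)
                break
    influential = tuple(influential)
    free = tuple(n for n in inputs if n not in influential)
    infl_idx = [inputs.index(n) for n in influential]

    groups: dict[tuple[int, ...], list[SimulationResult]] = {}
    for vector, res in sorted(by_vector.items()):
        groups.setdefault(tuple(vector[i] for i in infl_idx), []).append(res)

    classes = []
    for states, members in sorted(groups.items()):
        outcomes = {_outcome_key(r) for r in members}
        if len(outcomes) != 1:
            raise AssertionError(
                "free-input detection violated: class members disagree on outcome"
            )
        rep = members[0]
        classes.append(
            EquivalenceClass(
                fixed_states=tuple(zip(influential, states)),
                size=len(members),
                phenotype=rep.phenotype,
                phenotype_levels=rep.phenotype_levels,
            )
        )
    return EquivalenceClassTable(
        influential_inputs=influential, free_inputs=free, classes=tuple(classes)
    )


def extract_driver_signature(table: EquivalenceClassTable) -> DriverSignature:
    """The influential input states of the unique maximal-phenotype class.

    With a constant-output model the signature is empty; when several classes
    tie for the maximum, all tied classes are reported and no unique
    direction is claimed.
    """
    if not table.classes:
        raise ValueError("empty equivalence-class table")
    leveled = [c for c in table.classes if c.phenotype is not None]
    if not leveled:
        raise ValueError("no fixed-point class to rank")
    top = max(c.phenotype for c in leveled)
    maximal = tuple(c for c in leveled if c.phenotype == top)
    if not table.influential_inputs:
        return DriverSignature(inputs=(), direction=(), level=top)
    if len(maximal) > 1:
        return DriverSignature(
            inputs=table.influential_inputs, direction=(), level=top, tied=maximal
        )
    states = dict(maximal[0].fixed_states)
    return DriverSignature(
        inputs=table.influential_inputs,
        direction=tuple("high" if states[n] else "low" for n in table.influential_inputs),
        level=top,
    )


def random_signatures(
    core: RegulatoryCore | RegulatoryNetwork,
    count: int,
    size: int,
    seed: int,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """``count`` distinct random node subsets with arbitrary high/low labels.

    Node sets are sampled without replacement within each subset and subsets
    are pairwise distinct; fully reproducible from the seed.
    """
    net = core.network if isinstance(core, RegulatoryCore) else core
    nodes = list(net.nodes)
    if size > len(nodes):
        raise ValueError(f"signature size {size} exceeds core size {len(nodes)}")
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    guard = 0
    while len(out) < count:
        subset = tuple(sorted(rng.choice(nodes, size=size, replace=False)))
        guard += 1
        if guard > 1000 * count:
            raise ValueError("cannot draw enough distinct subsets; core too small")
        if subset in seen:
            continue
        seen.add(subset)
        directions = tuple(rng.choice(["high", "low"]) for _ in subset)
        out.append((subset, directions))
    return out


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def write_equivalence_classes(table: EquivalenceClassTable, path: str | Path) -> None:
    header = [*table.influential_inputs, "free_inputs", "class_size", "phenotype"]
    lines = ["\t".join(header)]
    for cls in table.classes:
        states = dict(cls.fixed_states)
        level = str(cls.phenotype) if cls.phenotype is not None else (
            "/".join(map(str, cls.phenotype_levels)) or "NA"
        )
        lines.append(
            "\t".join(
                [str(states[n]) for n in table.influential_inputs]
                + [",".join(table.free_inputs) or "-", str(cls.size), level]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_signature(signature: DriverSignature, path: str | Path) -> None:
    lines = ["gene\tdirection"]
    directions = signature.direction or ("ambiguous",) * len(signature.inputs)
    for gene, direction in zip(signature.inputs, directions):
        lines.append(f"{gene}\t{direction}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_random_signatures(
    signatures: list[tuple[tuple[str, ...], tuple[str, ...]]], path: str | Path
) -> None:
    lines = ["signature_id\tgenes\tdirections"]
    for idx, (genes, directions) in enumerate(signatures, start=1):
        lines.append(f"{idx}\t{','.join(genes)}\t{','.join(directions)}")
    Path(path).write_text("\n".join(lines) + "\n")
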