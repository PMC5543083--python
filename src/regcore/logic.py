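"""Three-layer logic models: Boolean regulatory rules with a multi-valued
phenotype output, synchronous steady states, input-space sweeps, and clamped
perturbation scans.

A model has three disjoint layers.  Input nodes are clamped to the chosen
input vector and never updated.  Regulatory nodes update synchronously,
``X_i(t+1) = BF_i(X(t))``, from an all-zero initial regulatory state, until a
fixed point or a revisited state (a cycle, which is reported, never hidden).
The single output node is *multi-valued*: its ordinal level (0..3) is the sum
of three Boolean factor expressions over marker states, e.g. for the bladder
model

    EMT = [(SMAD2/3/4 AND SNAI1) OR (ZEB1 AND TWIST1)] + (NOT CDH1) + FGFR1

Rule files use a BoolNet-style text dialect: a ``targets, factors`` table of
``node, expression`` lines with AND/OR/NOT (or &, |, !) and parentheses, plus
header lines declaring the input layer and the phenotype factors.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assembly import RegulatoryCore
from .network import Effect, RegulatoryNetwork
from .scoring import ExpressionContrast

KNOCKOUT = "knockout"
ACTIVATION = "activation"

# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|&{1,2}|\|{1,2}|!|[A-Za-z0-9_/.:+\-]+)")
_KEYWORDS = {"AND": "&", "OR": "|", "NOT": "!", "and": "&", "or": "|", "not": "!"}


class RuleParseError(ValueError):
    """Raised when a rule expression or model file cannot be parsed."""


class BoolExpr:
    """AST for a Boolean rule: nested ('and'|'or'|'not'|'var'|'const', ...)."""

    __slots__ = ("op", "args")

    def __init__(self, op: str, args: tuple):
        self.op = op
        self.args = args

    def evaluate(self, state: Mapping[str, int]) -> int:
        op = self.op
        if op == "var":
            name = self.args[0]
            if name not in state:
                raise KeyError(f"node {name!r} has no state")
            return 1 if state[name] else 0
        if op == "const":
            return self.args[0]
        if op == "not":
            return 1 - self.args[0].evaluate(state)
        if op == "and":
            return int(all(a.evaluate(state) for a in self.args))
        if op == "or":
            return int(any(a.evaluate(state) for a in self.args))
        raise AssertionError(op)

    def variables(self) -> set[str]:
        if self.op == "var":
            return {self.args[0]}
        if self.op == "const":
            return set()
        return set().union(*(a.variables() for a in self.args))

    def __repr__(self) -> str:
        return f"BoolExpr({unparse(self)!r})"


def unparse(expr: BoolExpr) -> str:
    if expr.op == "var":
        return expr.args[0]
    if expr.op == "const":
        return str(expr.args[0])
    if expr.op == "not":
        inner = unparse(expr.args[0])
        if expr.args[0].op in ("and", "or"):
            inner = f"({inner})"
        return f"NOT {inner}"
    joiner = " AND " if expr.op == "and" else " OR "
    parts = []
    for a in expr.args:
        text = unparse(a)
        if a.op in ("and", "or") and a.op != expr.op:
            text = f"({text})"
        parts.append(text)
    return joiner.join(parts)


def parse_expr(text: str) -> BoolExpr:
    """Parse AND/OR/NOT expressions with parentheses (also &, |, !, 0, 1).

    Precedence: NOT > AND > OR.  Identifiers may contain letters, digits and
    ``_ / . : + -`` so gene symbols like ``SMAD2/3/4`` or ``miR-25`` parse
    as single tokens.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise RuleParseError(f"cannot tokenize {text!r} at offset {pos}")
        tok = m.group(1)
        tokens.append(_KEYWORDS.get(tok, tok))
        pos = m.end()
    tokens = [{"&&": "&", "||": "|"}.get(t, t) for t in tokens]

    def parse_or(i: int) -> tuple[BoolExpr, int]:
        node, i = parse_and(i)
        args = [node]
        while i < len(tokens) and tokens[i] == "|":
            nxt, i = parse_and(i + 1)
            args.append(nxt)
        return (args[0] if len(args) == 1 else BoolExpr("or", tuple(args))), i

    def parse_and(i: int) -> tuple[BoolExpr, int]:
        node, i = parse_unary(i)
        args = [node]
        while i < len(tokens) and tokens[i] == "&":
            nxt, i = parse_unary(i + 1)
            args.append(nxt)
        return (args[0] if len(args) == 1 else BoolExpr("and", tuple(args))), i

    def parse_unary(i: int) -> tuple[BoolExpr, int]:
        if i >= len(tokens):
            raise RuleParseError(f"unexpected end of expression in {text!r}")
        tok = tokens[i]
        if tok == "!":
            inner, i = parse_unary(i + 1)
            return BoolExpr("not", (inner,)), i
        if tok == "(":
            inner, i = parse_or(i + 1)
            if i >= len(tokens) or tokens[i] != ")":
                raise RuleParseError(f"unbalanced parentheses in {text!r}")
            return inner, i + 1
        if tok in {")", "&", "|"}:
            raise RuleParseError(f"unexpected token {tok!r} in {text!r}")
        if tok in {"0", "1"}:
            return BoolExpr("const", (int(tok),)), i + 1
        return BoolExpr("var", (tok,)), i + 1

    expr, i = parse_or(0)
    if i != len(tokens):
        raise RuleParseError(f"trailing tokens {tokens[i:]} in {text!r}")
    return expr


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeRule:
    """Multi-valued output: level = factor1 + factor2 + factor3, each Boolean."""

    output: str
    factors: tuple[BoolExpr, ...]

    def evaluate(self, state: Mapping[str, int]) -> int:
        try:
            return sum(f.evaluate(state) for f in self.factors)
        except KeyError as exc:
            raise KeyError(f"phenotype marker missing from state: {exc}") from exc

    def markers(self) -> set[str]:
        return set().union(*(f.variables() for f in self.factors))


def evaluate_phenotype(state: Mapping[str, int], rule: PhenotypeRule) -> int:
    return rule.evaluate(state)


@dataclass
class LogicModel:
    """Ordered input layer, Boolean regulatory rules, optional phenotype rule."""

    inputs: tuple[str, ...]
    rules: dict[str, BoolExpr]
    phenotype: PhenotypeRule | None = None
    name: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.inputs) & set(self.rules)
        if overlap:
            raise ValueError(f"input nodes cannot carry rules: {sorted(overlap)}")
        declared = set(self.inputs) | set(self.rules)
        for target, expr in self.rules.items():
            undeclared = expr.variables() - declared
            if undeclared:
                raise ValueError(
                    f"rule for {target!r} references undeclared nodes {sorted(undeclared)}"
                )
        if self.phenotype is not None:
            if self.phenotype.output in declared:
                raise ValueError("output node must be distinct from the other layers")
            undeclared = self.phenotype.markers() - declared
            if undeclared:
                raise ValueError(
                    f"phenotype rule references undeclared nodes {sorted(undeclared)}"
                )

    @property
    def regulatory_nodes(self) -> tuple[str, ...]:
        return tuple(self.rules)


@dataclass(frozen=True)
class Perturbation:
    """Clamp one or two nodes: knockout (0) or constitutive activation (1)."""

    targets: tuple[tuple[str, str], ...]  # ((node, mode), ...)

    def __post_init__(self) -> None:
        if not 1 <= len(self.targets) <= 2:
            raise ValueError("perturbations are of order 1 or 2")
        nodes = [n for n, _ in self.targets]
        if len(set(nodes)) != len(nodes):
            raise ValueError("perturbation targets must be distinct")
        for _, mode in self.targets:
            if mode not in (KNOCKOUT, ACTIVATION):
                raise ValueError(f"unknown perturbation mode {mode!r}")

    def clamp_values(self) -> dict[str, int]:
        return {n: (0 if mode == KNOCKOUT else 1) for n, mode in self.targets}

    def label(self) -> str:
        return "+".join(f"{n}:{'KO' if m == KNOCKOUT else 'ACT'}" for n, m in self.targets)


@dataclass
class SimulationResult:
    input: dict[str, int]
    clamps: Perturbation | None
    attractor: tuple[dict[str, int], ...]  # one state (fixed point) or cycle states
    is_fixed_point: bool
    phenotype: int | None  # None when oscillatory
    phenotype_levels: tuple[int, ...] = field(default_factory=tuple)

    @property
    def oscillatory(self) -> bool:
        return not self.is_fixed_point

    @property
    def state(self) -> dict[str, int]:
        return self.attractor[0]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def steady_state(
    model: LogicModel,
    input_vector: Mapping[str, int],
    clamps: Perturbation | None = None,
    initial: Mapping[str, int] | None = None,
) -> SimulationResult:
    """Synchronous trajectory to a fixed point or a cycle.

    Inputs are clamped to ``input_vector``; regulatory nodes start at 0
    unless ``initial`` overrides; clamped nodes are never updated.  Cycles
    are detected by state hashing (a repeat must occur within 2^n steps) and
    reported with per-state phenotype levels instead of a single level.
    """
    missing = set(model.inputs) - set(input_vector)
    if missing:
        raise ValueError(f"input vector does not cover inputs {sorted(missing)}")
    clamp_values = clamps.clamp_values() if clamps else {}
    for node in clamp_values:
        if node not in model.rules and node not in model.inputs:
            raise KeyError(f"clamped node {node!r} is not in the model")

    state: dict[str, int] = {n: int(input_vector[n]) for n in model.inputs}
    for n in model.rules:
        state[n] = int(initial[n]) if initial and n in initial else 0
    state.update(clamp_values)

    order = list(model.rules)
    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[dict[str, int]] = []
    limit = 2 ** len(order) + 2
    for step in range(limit):
        key = tuple(state[n] for n in order)
        if key in seen:
            cycle_states = trajectory[seen[key]:]
            break
        seen[key] = step
        trajectory.append(dict(state))
        nxt = dict(state)
        for n in order:
            if n not in clamp_values:
                nxt[n] = model.rules[n].evaluate(state)
        state = nxt
    else:  # pragma: no cover - unreachable: repeats are guaranteed within 2^n
        raise RuntimeError("state space exhausted without a repeat")

    is_fixed = len(cycle_states) == 1
    attractor = tuple(cycle_states)
    if model.phenotype is None:
        levels: tuple[int, ...] = ()
        phenotype = None
    else:
        levels = tuple(model.phenotype.evaluate(s) for s in attractor)
        phenotype = levels[0] if is_fixed else None
    return SimulationResult(
        input=dict(input_vector),
        clamps=clamps,
        attractor=attractor,
        is_fixed_point=is_fixed,
        phenotype=phenotype,
        phenotype_levels=levels,
    )


def enumerate_input_space(
    model: LogicModel, clamps: Perturbation | None = None
) -> list[SimulationResult]:
    """One steady-state result per input vector, in lexicographic order."""
    m = len(model.inputs)
    if m > 20:
        raise ValueError(
            f"{m} inputs give 2^{m} vectors; enumerate is capped at 20 inputs -- sample instead"
        )
    results = []
    for bits in itertools.product((0, 1), repeat=m):
        vector = dict(zip(model.inputs, bits))
        results.append(steady_state(model, vector, clamps=clamps))
    return results


def perturbation_scan(
    model: LogicModel,
    base_input: Mapping[str, int],
    max_order: int = 2,
) -> pd.DataFrame:
    """Phenotype outcome of every clamped single and double intervention.

    The baseline input must reach a fixed point.  Each regulatory node is
    clamped to 0 (knockout) and 1 (activation); order-2 rows cover every
    unordered node pair in every mode combination.  Rows are sorted by the
    phenotype reduction relative to baseline, strongest first.
    """
    if not 1 <= max_order <= 2:
        raise ValueError("max_order must be 1 or 2")
    baseline = steady_state(model, base_input)
    if not baseline.is_fixed_point:
        raise ValueError("baseline input does not reach a fixed point")
    base_level = baseline.phenotype

    rows: list[dict] = []

    def record(pert: Perturbation | None) -> None:
        res = steady_state(model, base_input, clamps=pert)
        level = res.phenotype
        rows.append(
            {
                "targets": pert.label() if pert else "baseline",
                "order": len(pert.targets) if pert else 0,
                "phenotype": level if level is not None else float("nan"),
                "oscillatory": res.oscillatory,
                "reduction": (base_level - level) if level is not None else float("nan"),
            }
        )

    record(None)
    nodes = list(model.rules)
    modes = (KNOCKOUT, ACTIVATION)
    for node in nodes:
        for mode in modes:
            record(Perturbation(((node, mode),)))
    if max_order == 2:
        for a, b in itertools.combinations(nodes, 2):
            for mode_a in modes:
                for mode_b in modes:
                    record(Perturbation(((a, mode_a), (b, mode_b))))

    df = pd.DataFrame(rows)
    return df.sort_values(
        ["reduction", "order", "targets"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# rule derivation from a regulatory core
# ---------------------------------------------------------------------------

def derive_boolean_rules(
    core: RegulatoryCore | RegulatoryNetwork,
    contrast: ExpressionContrast,
    overrides: Mapping[str, str] | None = None,
    inputs: Sequence[str] | None = None,
    phenotype: PhenotypeRule | None = None,
) -> LogicModel:
    """Template Boolean rules from core structure and the expression contrast.

    Default template: a node is ON iff (OR over its activators) AND NOT
    (dominance expression over its inhibitors).  Dominant inhibitors are the
    ones upregulated in the invasive contrast (fc > 0); two or more dominant
    inhibitors combine with AND (they must cooperate to repress, mirroring
    how SNAI1 and TWIST1 jointly silence CDH1), a single one stands alone,
    and with no dominant inhibitor all inhibitors combine with OR.
    Unknown-effect edges are ignored.  ``overrides`` (node -> expression
    text) replace template rules verbatim.
    """
    net = core.network if isinstance(core, RegulatoryCore) else core
    overrides = dict(overrides or {})
    if inputs is None:
        indeg = {n: 0 for n in net.nodes}
        for ia in net.interactions:
            if ia.effect is not Effect.UNKNOWN:
                indeg[ia.target] += 1
        inputs = tuple(sorted(n for n, d in indeg.items() if d == 0))
    inputs = tuple(inputs)

    for node in overrides:
        if node not in net:
            raise KeyError(f"override for unknown node {node!r}")

    activators: dict[str, list[str]] = {n: [] for n in net.nodes}
    inhibitors: dict[str, list[str]] = {n: [] for n in net.nodes}
    for ia in net.interactions:
        if ia.effect is Effect.ACTIVATION:
            activators[ia.target].append(ia.source)
        elif ia.effect is Effect.INHIBITION:
            inhibitors[ia.target].append(ia.source)

    rules: dict[str, BoolExpr] = {}
    for node in net.nodes:
        if node in inputs:
            continue
        if node in overrides:
            rules[node] = parse_expr(overrides[node])
            continue
        acts = sorted(set(activators[node]))
        inhs = sorted(set(inhibitors[node]))
        if not acts and not inhs:
            raise ValueError(
                f"node {node!r} has neither regulators nor an override"
            )
        parts = []
        if acts:
            parts.append(" OR ".join(acts) if len(acts) > 1 else acts[0])
            if len(acts) > 1 and inhs:
                parts[0] = f"({parts[0]})"
        if inhs:
            dominant = [g for g in inhs if contrast.fc_for(g) > 0]
            chosen = dominant if dominant else inhs
            joiner = " AND " if len(dominant) >= 2 else " OR "
            inner = joiner.join(chosen) if len(chosen) > 1 else chosen[0]
            parts.append(f"NOT ({inner})" if len(chosen) > 1 else f"NOT {inner}")
        rules[node] = parse_expr(" AND ".join(parts))

    return LogicModel(inputs=inputs, rules=rules, phenotype=phenotype)


# ---------------------------------------------------------------------------
# model file IO
# ---------------------------------------------------------------------------

def loads_model(text: str, name: str = "") -> LogicModel:
    """Parse the rule-file dialect (see module docstring and data/ fixtures)."""
    inputs: tuple[str, ...] = ()
    output = None
    factors: list[BoolExpr] = []
    rules: dict[str, BoolExpr] = {}
    in_table = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        lowered = line.lower()
        if lowered.startswith("inputs:"):
            inputs = tuple(t.strip() for t in line.split(":", 1)[1].split(",") if t.strip())
        elif lowered.startswith("output:"):
            output = line.split(":", 1)[1].strip()
        elif lowered.startswith(("factor1:", "factor2:", "factor3:")):
            factors.append(parse_expr(line.split(":", 1)[1]))
        elif lowered.replace(" ", "") == "targets,factors":
            in_table = True
        elif in_table:
            if "," not in line:
                raise RuleParseError(f"line {lineno}: expected 'target, expression'")
            target, expr_text = line.split(",", 1)
            target = target.strip()
            if target in rules:
                raise RuleParseError(f"line {lineno}: duplicate rule for {target!r}")
            rules[target] = parse_expr(expr_text)
        else:
            raise RuleParseError(f"line {lineno}: unexpected line {line!r}")
    if not rules:
        raise RuleParseError("model file declares no regulatory rules")
    phenotype = None
    if output is not None:
        if not factors:
            raise RuleParseError(f"output {output!r} declared without factors")
        phenotype = PhenotypeRule(output=output, factors=tuple(factors))
    return LogicModel(inputs=inputs, rules=rules, phenotype=phenotype, name=name)


def load_model(path: str | Path) -> LogicModel:
    path = Path(path)
    return loads_model(path.read_text(), name=path.stem)


def write_model(model: LogicModel, path: str | Path) -> None:
    lines = []
    if model.inputs:
        lines.append("inputs: " + ", ".join(model.inputs))
    if model.phenotype is not None:
        lines.append(f"output: {model.phenotype.output}")
        for i, f in enumerate(model.phenotype.factors, start=1):
            lines.append(f"factor{i}: {unparse(f)}")
    lines.append("targets, factors")
    for target, expr in model.rules.items():
        lines.append(f"{target}, {unparse(expr)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(results: list[SimulationResult], path: str | Path) -> None:
    """Sweep results as TSV: input bits, attractor type, phenotype."""
    if not results:
        raise ValueError("no results to write")
    inputs = list(results[0].input)
    lines = ["\t".join(inputs) + "\tattractor\tphenotype"]
    for res in results:
        bits = "\t".join(str(res.input[i]) for i in inputs)
        kind = "fixed_point" if res.is_fixed_point else f"cycle[{len(res.attractor)}]"
        level = str(res.phenotype) if res.phenotype is not None else (
            "/".join(map(str, res.phenotype_levels)) or "NA"
        )
        lines.append(f"{bits}\t{kind}\t{level}")
    Path(path).write_text("\n".join(lines) + "\n")
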