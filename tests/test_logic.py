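"""Logic engine: rule parsing, synchronous steady states, sweeps, scans."""

import itertools

import numpy as np
import pytest

from regcore.assembly import RegulatoryCore, connect_components
from regcore.logic import (
    ACTIVATION,
    KNOCKOUT,
    LogicModel,
    Perturbation,
    PhenotypeRule,
    RuleParseError,
    derive_boolean_rules,
    enumerate_input_space,
    evaluate_phenotype,
    loads_model,
    parse_expr,
    perturbation_scan,
    steady_state,
    unparse,
    write_model,
)
from regcore.scoring import ExpressionContrast

from conftest import build_network


class TestExpressionParsing:
    @pytest.mark.parametrize(
        "text,state,expected",
        [
            ("A AND B", {"A": 1, "B": 1}, 1),
            ("A AND B", {"A": 1, "B": 0}, 0),
            ("A OR B AND C", {"A": 0, "B": 1, "C": 1}, 1),  # AND binds tighter
            ("(A OR B) AND C", {"A": 1, "B": 0, "C": 0}, 0),
            ("NOT A", {"A": 0}, 1),
            ("NOT (A AND B)", {"A": 1, "B": 0}, 1),
            ("!A & B | C", {"A": 1, "B": 1, "C": 0}, 0),
            ("SMAD2/3/4 AND miR-25", {"SMAD2/3/4": 1, "miR-25": 1}, 1),
            ("1 OR A", {"A": 0}, 1),
        ],
    )
    def test_evaluation(self, text, state, expected):
        assert parse_expr(text).evaluate(state) == expected

    @pytest.mark.parametrize("bad", ["A AND", "(A OR B", "AND A", "A B"])
    def test_malformed_expressions_rejected(self, bad):
        with pytest.raises(RuleParseError):
            parse_expr(bad)

    def test_unparse_round_trip(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            expr = _random_expr(rng, ["A", "B", "C", "D"], depth=3)
            again = parse_expr(unparse(expr))
            for bits in itertools.product((0, 1), repeat=4):
                state = dict(zip("ABCD", bits))
                assert again.evaluate(state) == expr.evaluate(state)


def _random_expr(rng, variables, depth):
    if depth == 0 or rng.random() < 0.3:
        return parse_expr(str(rng.choice(variables)))
    op = rng.choice(["and", "or", "not"])
    if op == "not":
        inner = _random_expr(rng, variables, depth - 1)
        return parse_expr(f"NOT ({unparse(inner)})")
    a = _random_expr(rng, variables, depth - 1)
    b = _random_expr(rng, variables, depth - 1)
    word = "AND" if op == "and" else "OR"
    return parse_expr(f"({unparse(a)}) {word} ({unparse(b)})")


class TestModelStructure:
    def test_inputs_cannot_carry_rules(self):
        with pytest.raises(ValueError, match="input nodes"):
            LogicModel(inputs=("A",), rules={"A": parse_expr("A")})

    def test_undeclared_reference_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            LogicModel(inputs=("A",), rules={"B": parse_expr("GHOST")})

    def test_model_file_round_trip(self, tmp_path, bladder_model):
        path = tmp_path / "model.txt"
        write_model(bladder_model, path)
        again = loads_model(path.read_text())
        assert again.inputs == bladder_model.inputs
        assert set(again.rules) == set(bladder_model.rules)
        sweep_a = enumerate_input_space(bladder_model)
        sweep_b = enumerate_input_space(again)
        assert [r.phenotype for r in sweep_a] == [r.phenotype for r in sweep_b]


class TestSteadyState:
    def test_bladder_all_inputs_off_is_level_zero(self, bladder_model):
        inputs = {n: 0 for n in bladder_model.inputs}
        res = steady_state(bladder_model, inputs)
        assert res.is_fixed_point
        assert res.phenotype == 0

    def test_bladder_three_drivers_reach_level_three(self, bladder_model):
        inputs = {n: 0 for n in bladder_model.inputs}
        inputs.update(E2F1=1, TGFBR1=1, FGFR1=1)
        res = steady_state(bladder_model, inputs)
        assert res.phenotype == 3

    def test_fixed_point_satisfies_rules_exactly(self, bladder_model, breast_model):
        for model in (bladder_model, breast_model):
            for res in enumerate_input_space(model):
                assert res.is_fixed_point
                state = res.state
                for node, rule in model.rules.items():
                    assert state[node] == rule.evaluate(state)

    def test_clamped_nodes_keep_their_clamp(self, bladder_model):
        inputs = {n: 1 for n in bladder_model.inputs}
        pert = Perturbation((("ZEB1", KNOCKOUT), ("CDH1", ACTIVATION)))
        res = steady_state(bladder_model, inputs, clamps=pert)
        assert res.state["ZEB1"] == 0
        assert res.state["CDH1"] == 1

    def test_cycle_reported_not_hidden(self):
        model = LogicModel(inputs=(), rules={"A": parse_expr("NOT A")})
        res = steady_state(model, {})
        assert res.oscillatory
        assert len(res.attractor) == 2
        assert res.phenotype is None

    def test_missing_input_rejected(self, bladder_model):
        with pytest.raises(ValueError, match="does not cover"):
            steady_state(bladder_model, {"E2F1": 1})

    @pytest.mark.parametrize("seed", range(30))
    def test_attractor_matches_exhaustive_state_graph_oracle(self, seed):
        """Synchronous attractors equal the full 2^n transition-graph walk."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        regs = [f"R{i}" for i in range(n)]
        inputs = ("I0",)
        rules = {
            r: _random_expr(rng, regs + ["I0"], depth=2) for r in regs
        }
        model = LogicModel(inputs=inputs, rules=rules)
        bit = int(rng.integers(0, 2))
        res = steady_state(model, {"I0": bit})

        # oracle: independent python-eval over the explicit transition table
        py_rules = {
            r: _to_python(rules[r]) for r in regs
        }
        state = {r: 0 for r in regs}
        state["I0"] = bit
        seen = {}
        trail = []
        while tuple(state[r] for r in regs) not in seen:
            key = tuple(state[r] for r in regs)
            seen[key] = len(trail)
            trail.append(key)
            nxt = {r: int(eval(py_rules[r], {}, dict(state))) for r in regs}
            nxt["I0"] = bit
            state = nxt
        cycle = trail[seen[tuple(state[r] for r in regs)]:]

        got = [tuple(s[r] for r in regs) for s in res.attractor]
        assert len(got) == len(cycle)
        assert set(got) == set(cycle)
        assert res.is_fixed_point == (len(cycle) == 1)


def _to_python(expr):
    text = unparse(expr)
    return (
        text.replace("AND", "and").replace("OR", "or").replace("NOT", "not")
    )


class TestPhenotypeRule:
    def _rule(self):
        return PhenotypeRule(
            output="EMT",
            factors=(
                parse_expr("(SMAD2/3/4 AND SNAI1) OR (ZEB1 AND TWIST1)"),
                parse_expr("NOT CDH1"),
                parse_expr("FGFR1"),
            ),
        )

    def test_level_three_state(self):
        state = {"SMAD2/3/4": 1, "SNAI1": 1, "ZEB1": 0, "TWIST1": 0,
                 "CDH1": 0, "FGFR1": 1}
        assert evaluate_phenotype(state, self._rule()) == 3

    def test_epithelial_ground_state(self):
        state = {"SMAD2/3/4": 0, "SNAI1": 0, "ZEB1": 0, "TWIST1": 0,
                 "CDH1": 1, "FGFR1": 0}
        assert evaluate_phenotype(state, self._rule()) == 0

    def test_factor_one_only(self):
        state = {"SMAD2/3/4": 0, "SNAI1": 0, "ZEB1": 1, "TWIST1": 1,
                 "CDH1": 1, "FGFR1": 0}
        assert evaluate_phenotype(state, self._rule()) == 1

    def test_missing_marker_is_an_error(self):
        with pytest.raises(KeyError):
            evaluate_phenotype({"CDH1": 1}, self._rule())


class TestInputSpace:
    def test_bladder_has_64_vectors(self, bladder_model):
        assert len(enumerate_input_space(bladder_model)) == 64

    def test_breast_has_128_vectors(self, breast_model):
        assert len(enumerate_input_space(breast_model)) == 128

    def test_zero_inputs_single_result(self):
        model = LogicModel(inputs=(), rules={"A": parse_expr("A")})
        assert len(enumerate_input_space(model)) == 1

    def test_lexicographic_order(self, bladder_model):
        results = enumerate_input_space(bladder_model)
        bits = [tuple(r.input[i] for i in bladder_model.inputs) for r in results]
        assert bits == sorted(bits)

    def test_too_many_inputs_advises_sampling(self):
        inputs = tuple(f"I{i}" for i in range(21))
        model = LogicModel(inputs=inputs, rules={"R": parse_expr("I0")})
        with pytest.raises(ValueError, match="sample"):
            enumerate_input_space(model)

    @pytest.mark.parametrize(
        "model_fixture,drivers",
        [
            ("bladder_model", ("E2F1", "TGFBR1", "FGFR1")),
            ("breast_model", ("E2F1", "TGFBR2", "EGFR")),
        ],
    )
    def test_phenotype_counts_active_drivers(self, model_fixture, drivers, request):
        """Across the whole sweep the level equals the number of active drivers."""
        model = request.getfixturevalue(model_fixture)
        for res in enumerate_input_space(model):
            assert res.phenotype == sum(res.input[d] for d in drivers)


class TestPerturbationScan:
    def test_baseline_row_repeats_baseline_level(self, bladder_model):
        inputs = {n: 0 for n in bladder_model.inputs}
        inputs.update(E2F1=1, TGFBR1=1, FGFR1=1)
        scan = perturbation_scan(bladder_model, inputs)
        baseline = scan[scan["order"] == 0]
        assert baseline["phenotype"].tolist() == [3]

    def test_bladder_smad_twist_double_knockout(self, bladder_model):
        inputs = {n: 0 for n in bladder_model.inputs}
        inputs.update(E2F1=1, TGFBR1=1, FGFR1=1)
        res = steady_state(
            bladder_model, inputs,
            clamps=Perturbation((("SMAD2/3/4", KNOCKOUT), ("TWIST1", KNOCKOUT))),
        )
        assert res.phenotype == 1

    def test_breast_src_fn1_double_knockout(self, breast_model):
        inputs = {n: 0 for n in breast_model.inputs}
        inputs.update(E2F1=1, TGFBR2=1, EGFR=1)
        res = steady_state(
            breast_model, inputs,
            clamps=Perturbation((("SRC", KNOCKOUT), ("FN1", KNOCKOUT))),
        )
        assert res.phenotype == 1

    def test_scan_covers_singles_and_pairs_sorted_by_reduction(self, bladder_model):
        inputs = {n: 0 for n in bladder_model.inputs}
        inputs.update(E2F1=1, TGFBR1=1, FGFR1=1)
        scan = perturbation_scan(bladder_model, inputs, max_order=2)
        k = len(bladder_model.rules)
        assert len(scan) == 1 + 2 * k + 4 * (k * (k - 1) // 2)
        reductions = scan["reduction"].dropna().tolist()
        assert reductions == sorted(reductions, reverse=True)

    def test_upstream_nodes_untouched_by_downstream_clamp(self):
        # chain I -> A -> B -> C: clamping C cannot change A or B
        model = LogicModel(
            inputs=("I",),
            rules={"A": parse_expr("I"), "B": parse_expr("A"), "C": parse_expr("B")},
        )
        free = steady_state(model, {"I": 1})
        clamped = steady_state(model, {"I": 1},
                               clamps=Perturbation((("C", KNOCKOUT),)))
        assert clamped.state["A"] == free.state["A"]
        assert clamped.state["B"] == free.state["B"]


class TestRuleDerivation:
    def _contrast(self, up, down):
        return ExpressionContrast(fc={**{g: 1.5 for g in up}, **{g: -1.5 for g in down}})

    def test_single_activator_passes_through(self):
        net = build_network([("A", "B", "activation")])
        model = derive_boolean_rules(net, ExpressionContrast(fc={}), inputs=("A",))
        assert unparse(model.rules["B"]) == "A"

    def test_cdh1_dominant_inhibitors_combine_with_and(self):
        """Six inhibitors, two upregulated: the rule keeps only the dominant
        pair, joined with AND."""
        inhibitors = ["SNAI1", "SNAI2", "TWIST1", "SRC", "miR-25", "MDM2"]
        net = build_network([(g, "CDH1", "inhibition") for g in inhibitors])
        contrast = self._contrast(
            up=["SNAI1", "TWIST1"], down=["SNAI2", "SRC", "miR-25", "MDM2"]
        )
        model = derive_boolean_rules(net, contrast, inputs=tuple(inhibitors))
        assert unparse(model.rules["CDH1"]) == "NOT (SNAI1 AND TWIST1)"

    def test_single_dominant_inhibitor_stands_alone(self):
        net = build_network(
            [("X", "T", "inhibition"), ("Y", "T", "inhibition"), ("A", "T", "activation")]
        )
        model = derive_boolean_rules(
            net, self._contrast(up=["X"], down=["Y"]), inputs=("A", "X", "Y")
        )
        assert unparse(model.rules["T"]) == "A AND NOT X"

    def test_no_dominant_inhibitor_falls_back_to_or(self):
        net = build_network([("X", "T", "inhibition"), ("Y", "T", "inhibition")])
        model = derive_boolean_rules(
            net, self._contrast(up=[], down=["X", "Y"]), inputs=("X", "Y")
        )
        assert unparse(model.rules["T"]) == "NOT (X OR Y)"

    def test_override_replaces_template(self):
        net = build_network([("A", "B", "activation"), ("C", "B", "inhibition")])
        model = derive_boolean_rules(
            net, ExpressionContrast(fc={}),
            overrides={"B": "A AND NOT C OR 1"}, inputs=("A", "C"),
        )
        assert model.rules["B"].evaluate({"A": 0, "C": 1}) == 1

    def test_orphan_regulatory_node_is_an_error(self):
        net = build_network([("A", "B", "activation")])
        net.add_node("LONER")
        with pytest.raises(ValueError, match="LONER"):
            derive_boolean_rules(net, ExpressionContrast(fc={}), inputs=("A",))

    def test_unknown_override_target_is_an_error(self, three_cycle):
        with pytest.raises(KeyError, match="GHOST"):
            derive_boolean_rules(
                three_cycle, ExpressionContrast(fc={}), overrides={"GHOST": "A"}
            )
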