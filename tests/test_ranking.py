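"""Multi-objective motif scoring and top-k selection."""

import numpy as np
import pytest

from regcore.loops import enumerate_feedback_loops, filter_loops
from regcore.network import NodeMetrics
from regcore.ranking import (
    MotifFeatures,
    WeightingScenario,
    default_scenarios,
    motif_features,
    rank_and_select,
    score_motifs,
    validate_score_bounds,
)
from regcore.scoring import ExpressionContrast, PathwayFlags, PrioritizationScore
from regcore.synthetic import SyntheticSpec, random_signed_network

from conftest import build_network

# Three-loop toy instance with hand-computed scores (weights 0.5/0.5/0/0):
#   S = 0.25*ND/8 + 0.25*BC/20 + 0.5*DP/3
TOY = {
    "L1": MotifFeatures(nd=4, bc=10, dp=1, gp=0.2, abs_fc=1.0),
    "L2": MotifFeatures(nd=8, bc=5, dp=3, gp=0.1, abs_fc=0.5),
    "L3": MotifFeatures(nd=2, bc=20, dp=2, gp=0.4, abs_fc=2.0),
}
TOY_EXPECTED = {"L1": 0.4166666667, "L2": 0.8125, "L3": 0.6458333333}


class TestScenarios:
    def test_default_set_has_13_valid_scenarios(self):
        scen = default_scenarios()
        assert len(scen) == 13
        for sc in scen:
            assert sum((sc.w1, sc.w2, sc.w3, sc.w4)) == pytest.approx(1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightingScenario(1, -0.1, 0.5, 0.3, 0.3)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WeightingScenario(1, 0.5, 0.5, 0.5, 0.0)


class TestFeatures:
    def _inputs(self, loop):
        metrics = NodeMetrics(
            degree={"A": 2, "B": 4, "C": 6},
            betweenness={"A": 0.0, "B": 1.0, "C": 2.0},
        )
        flags = PathwayFlags({"A": True, "B": True, "C": True})
        gp = PrioritizationScore({"A": 0.5, "B": 0.3, "C": 0.2})
        fc = ExpressionContrast(fc={"A": 1.0, "B": -1.0, "C": 2.0})
        return metrics, flags, gp, fc

    def test_means_and_counts(self, three_cycle):
        loop = enumerate_feedback_loops(three_cycle)[0]
        f = motif_features(loop, *self._inputs(loop))
        assert f.nd == pytest.approx(4.0)
        assert f.dp == 3
        assert f.abs_fc == pytest.approx(4.0 / 3.0)

    def test_missing_node_named_in_error(self, three_cycle):
        loop = enumerate_feedback_loops(three_cycle)[0]
        metrics, flags, gp, fc = self._inputs(loop)
        del gp.gp["B"]
        with pytest.raises(KeyError, match="'B'"):
            motif_features(loop, metrics, flags, gp, fc)


class TestScoring:
    def test_hand_computed_toy_table(self):
        scores = score_motifs(TOY, WeightingScenario(1, 0.5, 0.5, 0.0, 0.0))
        by_key = {s.motif_key: s.score for s in scores}
        for key, expected in TOY_EXPECTED.items():
            assert by_key[key] == pytest.approx(expected, abs=1e-9)

    def test_loop_attaining_every_maximum_scores_one(self):
        features = {
            "top": MotifFeatures(nd=8, bc=20, dp=3, gp=0.4, abs_fc=2.0),
            "other": MotifFeatures(nd=4, bc=10, dp=1, gp=0.2, abs_fc=1.0),
        }
        scores = score_motifs(features, WeightingScenario(1, 0.25, 0.25, 0.25, 0.25))
        assert {s.motif_key: s.score for s in scores}["top"] == pytest.approx(1.0)

    def test_all_zero_weights_score_zero(self):
        scores = score_motifs(TOY, WeightingScenario(1, 0, 0, 0, 0))
        assert all(s.score == 0.0 for s in scores)

    def test_zero_max_criterion_contributes_nothing(self):
        features = {
            "a": MotifFeatures(nd=2, bc=0.0, dp=0, gp=0.1, abs_fc=0.0),
            "b": MotifFeatures(nd=4, bc=0.0, dp=0, gp=0.2, abs_fc=0.0),
        }
        scores = score_motifs(features, WeightingScenario(1, 0.0, 0.5, 0.0, 0.5))
        assert all(s.score == 0.0 for s in scores)

    def test_scores_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        features = {
            f"L{i}": MotifFeatures(*rng.uniform(0.01, 10, size=5)) for i in range(30)
        }
        for sc in default_scenarios():
            validate_score_bounds(score_motifs(features, sc))

    def test_invariant_under_feature_rescaling(self):
        scaled = {
            k: MotifFeatures(f.nd * 100, f.bc, f.dp, f.gp, f.abs_fc)
            for k, f in TOY.items()
        }
        sc = WeightingScenario(1, 0.4, 0.2, 0.2, 0.2)
        original = {s.motif_key: s.score for s in score_motifs(TOY, sc)}
        rescaled = {s.motif_key: s.score for s in score_motifs(scaled, sc)}
        for key in TOY:
            assert rescaled[key] == pytest.approx(original[key])

    def test_monotone_in_gp_when_weighted(self):
        sc = WeightingScenario(1, 0.0, 0.0, 1.0, 0.0)
        base = {s.motif_key: s.score for s in score_motifs(TOY, sc)}
        boosted = dict(TOY)
        boosted["L1"] = MotifFeatures(4, 10, 1, 0.35, 1.0)
        after = {s.motif_key: s.score for s in score_motifs(boosted, sc)}
        assert after["L1"] > base["L1"]


class TestSelection:
    def test_dominating_loop_ranks_first_everywhere(self):
        features = {
            "dom": MotifFeatures(nd=9, bc=9, dp=3, gp=0.9, abs_fc=3.0),
            "x": MotifFeatures(nd=3, bc=3, dp=1, gp=0.1, abs_fc=1.0),
            "y": MotifFeatures(nd=1, bc=1, dp=0, gp=0.2, abs_fc=0.5),
        }
        for sc in default_scenarios():
            assert score_motifs(features, sc)[0].motif_key == "dom"

    def test_k_larger_than_pool_selects_all(self):
        by_scenario = {1: score_motifs(TOY, WeightingScenario(1, 1, 0, 0, 0))}
        assert rank_and_select(by_scenario, k=50) == sorted(TOY)

    def test_union_matches_bruteforce_reranking(self):
        """40 synthetic loops x 13 scenarios vs an independent full re-sort."""
        rng = np.random.default_rng(99)
        features = {
            f"M{i:02d}": MotifFeatures(*rng.uniform(0.0, 5.0, size=5))
            for i in range(40)
        }
        scenarios = default_scenarios()
        by_scenario = {sc.id: score_motifs(features, sc) for sc in scenarios}
        selected = rank_and_select(by_scenario, k=10)

        # independent oracle: recompute scores from raw features and sort
        expected = set()
        maxima = [max(getattr(f, a) for f in features.values())
                  for a in ("nd", "bc", "dp", "gp", "abs_fc")]
        for sc in scenarios:
            table = []
            for key, f in features.items():
                raw = [f.nd, f.bc, f.dp, f.gp, f.abs_fc]
                norm = [v / m if m else 0.0 for v, m in zip(raw, maxima)]
                s = (sc.w1 / 2 * (norm[0] + norm[1]) + sc.w2 * norm[2]
                     + sc.w3 * norm[3] + sc.w4 * norm[4])
                table.append((-s, -f.abs_fc, key))
            expected.update(key for _, _, key in sorted(table)[:10])
        assert set(selected) == expected

    def test_selection_deterministic_across_runs(self):
        net = random_signed_network(SyntheticSpec(n_nodes=18, edge_prob=0.25, seed=4))
        loops = filter_loops(enumerate_feedback_loops(net))
        rng = np.random.default_rng(1)
        features = {
            lp.canonical_key: MotifFeatures(*rng.uniform(0, 3, size=5)) for lp in loops
        }
        runs = [
            rank_and_select(
                {sc.id: score_motifs(features, sc) for sc in default_scenarios()}, k=5
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
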