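"""End-to-end pipeline: network -> loops -> scores -> core -> logic -> signatures.

Stages run in a fixed order, each writing its tabular output into the run
directory, and a machine-readable ``summary.json`` records the headline
counts.  Any stage failure aborts with the stage name and cause; outputs of
completed stages are retained.  With a fixed seed and config the whole run,
including the summary file, is byte-identical across invocations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assembly, loops as loops_mod, logic, ranking, scoring, signatures
from .network import compute_node_metrics, load_network, network_summary
from .scoring import ExpressionContrast
from .synthetic import default_emt_markers

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    network_path: str
    outdir: str
    seed: int = 0
    network_dialect: str = "sif"
    gene_set_path: str | None = None  # GMT
    gene_set_name: str | None = None
    expression_path: str | None = None  # genes x samples TSV
    invasive_samples: list[str] = field(default_factory=list)
    noninvasive_samples: list[str] = field(default_factory=list)
    fold_change_path: str | None = None  # precomputed (gene, log2fc) TSV
    seed_genes_path: str | None = None
    model_path: str | None = None  # explicit logic model; else derived from core
    rule_overrides: dict[str, str] = field(default_factory=dict)
    max_loop_length: int = 3
    include_self_loops: bool = False
    top_k: int = 10
    restart_prob: float = 0.7
    scenarios_path: str | None = None
    perturb_order: int = 2
    allow_two_step: bool = False
    n_random_signatures: int = 30
    random_signature_size: int = 3
    pseudocount: float = 0.0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return PipelineConfig(**raw)

    def validate_paths(self) -> None:
        for name in (
            "network_path", "gene_set_path", "expression_path", "fold_change_path",
            "seed_genes_path", "model_path", "scenarios_path",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    def stage(name: str):
        def decorator(fn):
            try:
                result = fn()
            except Exception as exc:
                _write_summary(summary, outdir)
                raise StageError(name, exc) from exc
            summary["stages"].append(name)
            return result

        return decorator

    @stage("load_network")
    def net():
        return load_network(config.network_path, dialect=config.network_dialect)

    @stage("metrics")
    def metrics():
        m = compute_node_metrics(net)
        stats = network_summary(net)
        summary["network"] = {
            "nodes": stats.node_count,
            "edges": stats.edge_count,
            "diameter": stats.diameter,
        }
        lines = ["node\tdegree\tbetweenness"]
        for node in net.nodes:
            lines.append(f"{node}\t{m.degree[node]}\t{m.betweenness[node]:.6g}")
        (outdir / "node_metrics.tsv").write_text("\n".join(lines) + "\n")
        return m

    @stage("loops")
    def all_loops():
        found = loops_mod.enumerate_feedback_loops(net, config.max_loop_length)
        loops_mod.write_loops(found, outdir / "loops.tsv")
        summary["loops"] = {"total": len(found), **loops_mod.sign_census(found)}
        kept = found if config.include_self_loops else loops_mod.filter_loops(found)
        if not kept:
            raise ValueError("no feedback loops of rankable length found")
        return {lp.canonical_key: lp for lp in kept}

    @stage("node_criteria")
    def criteria():
        if config.gene_set_path:
            sets = scoring.read_gmt(config.gene_set_path)
            name = config.gene_set_name or next(iter(sets))
            gene_set = sets[name]
        else:  # degenerate fallback: every node "in pathway"
            gene_set = list(net.nodes)
        flags = scoring.flag_pathway_membership(net, gene_set)

        if config.seed_genes_path:
            seeds = [
                s.strip()
                for s in Path(config.seed_genes_path).read_text().splitlines()
                if s.strip() and not s.startswith("#")
            ]
        else:
            seeds = [g for g in default_emt_markers() if g in net]
            if not seeds:  # synthetic networks: fall back to pathway genes
                seeds = [g for g in gene_set if g in net]
        gp = scoring.rwr_prioritize(net, seeds, restart_prob=config.restart_prob)

        if config.fold_change_path:
            contrast = scoring.read_fold_change_table(config.fold_change_path)
        elif config.expression_path:
            expr = scoring.read_expression_table(config.expression_path)
            contrast = scoring.fold_change_contrast(
                expr, config.invasive_samples, config.noninvasive_samples,
                pseudocount=config.pseudocount,
            )
        else:
            contrast = ExpressionContrast(fc={})
        return flags, gp, contrast

    flags, gp, contrast = criteria

    @stage("ranking")
    def selected_keys():
        metrics_ = metrics
        features = {
            key: ranking.motif_features(lp, metrics_, flags, gp, contrast)
            for key, lp in all_loops.items()
        }
        scen = (
            ranking.load_scenarios(config.scenarios_path)
            if config.scenarios_path
            else ranking.default_scenarios()
        )
        by_scenario = {}
        for sc in scen:
            scores = ranking.score_motifs(features, sc)
            ranking.write_scores(scores, outdir / f"scores_scenario{sc.id:02d}.tsv")
            by_scenario[sc.id] = scores
        keys = ranking.rank_and_select(by_scenario, k=config.top_k)
        (outdir / "selected_motifs.tsv").write_text(
            "canonical_key\n" + "\n".join(keys) + "\n"
        )
        summary["motifs_selected"] = len(keys)
        return keys

    @stage("core")
    def core():
        merged = assembly.merge_motifs(
            [all_loops[k] for k in selected_keys], categories=net.categories
        )
        built = assembly.connect_components(merged, net, allow_two_step=config.allow_two_step)
        assembly.write_core(built, outdir / "core_edges.tsv")
        assembly.write_component_labels(built, outdir / "core_components.tsv")
        summary["core"] = {
            "nodes": len(built.network),
            "edges": built.network.n_interactions,
            "bridges": len(built.bridge_edges),
        }
        return built

    @stage("logic_model")
    def model():
        if config.model_path:
            m = logic.load_model(config.model_path)
        else:
            m = logic.derive_boolean_rules(core, contrast, overrides=config.rule_overrides)
            if m.phenotype is None:
                m = _attach_default_phenotype(m, contrast)
        logic.write_model(m, outdir / "model.txt")
        summary["logic"] = {
            "inputs": len(m.inputs),
            "regulatory_nodes": len(m.rules),
            "input_space": 2 ** len(m.inputs),
        }
        return m

    @stage("sweep")
    def sweep():
        results = logic.enumerate_input_space(model)
        logic.write_results(results, outdir / "sweep.tsv")
        return results

    @stage("perturbations")
    def perturbations():
        fixed = [r for r in sweep if r.is_fixed_point and r.phenotype is not None]
        if not fixed:
            summary["perturbations"] = {"note": "no fixed-point baseline available"}
            return None
        best = max(fixed, key=lambda r: (r.phenotype, tuple(-v for v in r.input.values())))
        scan = logic.perturbation_scan(model, best.input, max_order=config.perturb_order)
        scan.to_csv(outdir / "perturbations.tsv", sep="\t", index=False)
        top = scan[scan["order"] > 0].head(5)
        summary["perturbations"] = {
            "baseline_level": best.phenotype,
            "top": [
                {"targets": r.targets, "phenotype": None if r.phenotype != r.phenotype else int(r.phenotype)}
                for r in top.itertuples()
            ],
        }
        return scan

    @stage("signatures")
    def signature():
        table = signatures.collapse_equivalence_classes(sweep)
        signatures.write_equivalence_classes(table, outdir / "equivalence_classes.tsv")
        controls = signatures.random_signatures(
            core, config.n_random_signatures, config.random_signature_size, config.seed
        )
        signatures.write_random_signatures(controls, outdir / "random_signatures.tsv")
        try:
            sig = signatures.extract_driver_signature(table)
        except ValueError:
            # every sweep outcome oscillatory: no level to rank
            summary["signature"] = {"note": "no fixed-point class to rank"}
            return None
        signatures.write_signature(sig, outdir / "signature.tsv")
        summary["signature"] = {
            "inputs": list(sig.inputs),
            "direction": list(sig.direction),
            "level": sig.level,
        }
        return sig

    _write_summary(summary, outdir)
    return summary


def _attach_default_phenotype(model: logic.LogicModel, contrast) -> logic.LogicModel:
    """Fallback output rule: the three regulatory nodes with the largest
    absolute fold-change (ties by name) become additive Boolean factors."""
    markers = sorted(
        model.rules, key=lambda n: (-contrast.abs_fc_for(n), n)
    )[:3]
    if not markers:
        return model
    rule = logic.PhenotypeRule(
        output="PHENOTYPE",
        factors=tuple(logic.parse_expr(m) for m in markers),
    )
    return logic.LogicModel(
        inputs=model.inputs, rules=model.rules, phenotype=rule, name=model.name
    )


def _write_summary(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
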