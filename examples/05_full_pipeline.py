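"""End-to-end pipeline on synthetic inputs.

Generates a network, gene set and expression table on disk, then runs every
stage (metrics -> loops -> criteria -> ranking -> core -> logic -> sweep ->
perturbations -> signatures) into a run directory with one TSV per stage and
a machine-readable summary.
"""

import json
import tempfile
from pathlib import Path

from regcore import (
    PipelineConfig,
    SyntheticSpec,
    random_signed_network,
    run_pipeline,
    synthetic_expression,
)

workdir = Path(tempfile.mkdtemp(prefix="regcore_demo_"))
net = random_signed_network(SyntheticSpec(n_nodes=30, edge_prob=0.12, seed=2024))
net.write(workdir / "network.sif")
genes = list(net.nodes)
(workdir / "cancer.gmt").write_text(
    "pathways_in_cancer\tsynthetic\t" + "\t".join(genes[:10]) + "\n"
)
table, inv, non = synthetic_expression(
    SyntheticSpec(n_nodes=30, planted_log2fc={genes[0]: 2.0}, seed=7), genes=genes
)
table.to_csv(workdir / "expression.tsv", sep="\t")

summary = run_pipeline(
    PipelineConfig(
        network_path=str(workdir / "network.sif"),
        outdir=str(workdir / "run"),
        seed=11,
        gene_set_path=str(workdir / "cancer.gmt"),
        expression_path=str(workdir / "expression.tsv"),
        invasive_samples=inv,
        noninvasive_samples=non,
        top_k=5,
    )
)
print("stages:", " -> ".join(summary["stages"]))
print(json.dumps({k: v for k, v in summary.items() if k != "stages"}, indent=2))
print(f"outputs in {workdir / 'run'}")
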