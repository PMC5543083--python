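"""Non-topological node criteria: pathway membership, random-walk
prioritization, and expression fold-change.

These three quantities, together with degree and betweenness, feed the
weighted multi-objective motif score.  The random walk with restart measures
proximity to a seed set (typically EMT marker genes); disease-pathway
membership flags nodes found in a curated gene set such as KEGG "Pathways in
cancer"; the expression contrast is a plain log2 ratio of group means between
an invasive and a non-invasive condition, standing in for (or accepting the
output of) an external differential-expression fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork


# ---------------------------------------------------------------------------
# random walk with restart
# ---------------------------------------------------------------------------

@dataclass
class PrioritizationScore:
    """Stationary random-walk probabilities; non-negative and summing to 1."""

    gp: dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.gp[node]


def rwr_prioritize(
    net: RegulatoryNetwork,
    seeds: list[str],
    restart_prob: float = 0.7,
    tol: float = 1e-10,
    directed: bool = False,
    max_iter: int = 100_000,
) -> PrioritizationScore:
    """Random walk with restart over the (by default undirected) skeleton.

    Iterates ``p <- (1 - r) W p + r p0`` with a column-stochastic transition
    matrix W and a uniform restart vector over the seeds, until the L1 change
    drops below ``tol``.  A dangling column (isolated node) keeps its mass in
    place (self-retention), so W stays stochastic without leaking probability
    to unreachable nodes.
    """
    if not 0 < restart_prob < 1:
        raise ValueError("restart_prob must lie in (0, 1)")
    nodes = net.nodes
    index = {n: i for i, n in enumerate(nodes)}
    present = [s for s in seeds if s in index]
    if not present:
        raise ValueError("no seed gene is present in the network")

    n = len(nodes)
    adj = np.zeros((n, n))
    for ia in net.interactions:
        adj[index[ia.target], index[ia.source]] = 1.0
        if not directed:
            adj[index[ia.source], index[ia.target]] = 1.0
    col_sums = adj.sum(axis=0)
    w = adj / np.where(col_sums > 0, col_sums, 1.0)
    for j in np.flatnonzero(col_sums == 0):
        w[j, j] = 1.0

    p0 = np.zeros(n)
    p0[[index[s] for s in present]] = 1.0 / len(present)
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1.0 - restart_prob) * (w @ p) + restart_prob * p0
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    p = p / p.sum()
    return PrioritizationScore(gp={node: float(p[index[node]]) for node in nodes})


# ---------------------------------------------------------------------------
# disease-pathway membership
# ---------------------------------------------------------------------------

@dataclass
class PathwayFlags:
    in_disease_pathway: dict[str, bool]

    def __getitem__(self, node: str) -> bool:
        return self.in_disease_pathway[node]


def flag_pathway_membership(net: RegulatoryNetwork, gene_set: list[str]) -> PathwayFlags:
    """Exact string match (after whitespace trimming) against a gene set."""
    if not gene_set:
        raise ValueError("gene set is empty")
    members = {g.strip() for g in gene_set}
    return PathwayFlags({node: node in members for node in net.nodes})


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line, ``name <tab> desc <tab> genes...``."""
    sets: dict[str, list[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {raw!r}")
        sets[parts[0]] = [g.strip() for g in parts[2:] if g.strip()]
    return sets


# ---------------------------------------------------------------------------
# expression fold-change contrast
# ---------------------------------------------------------------------------

@dataclass
class ExpressionContrast:
    """Per-gene signed log2 fold-change (invasive vs non-invasive).

    Genes absent from the expression table carry fc = 0 and are recorded in
    ``missing`` once queried.
    """

    fc: dict[str, float]
    missing: set[str] = field(default_factory=set)

    def fc_for(self, gene: str) -> float:
        if gene not in self.fc:
            self.missing.add(gene)
            return 0.0
        return self.fc[gene]

    def abs_fc_for(self, gene: str) -> float:
        return abs(self.fc_for(gene))


def fold_change_contrast(
    expr: pd.DataFrame,
    invasive_samples: list[str],
    noninvasive_samples: list[str],
    pseudocount: float = 0.0,
) -> ExpressionContrast:
    """log2((mean_invasive + pc) / (mean_noninvasive + pc)) per gene.

    ``expr`` is genes x samples (gene identifiers in the index).  Antisymmetric
    under swapping the two groups.
    """
    if not invasive_samples or not noninvasive_samples:
        raise ValueError("both sample groups must be non-empty")
    for sample in [*invasive_samples, *noninvasive_samples]:
        if sample not in expr.columns:
            raise KeyError(f"sample {sample!r} not in expression table")
    mean_inv = expr[invasive_samples].mean(axis=1) + pseudocount
    mean_non = expr[noninvasive_samples].mean(axis=1) + pseudocount
    fc = np.log2(mean_inv / mean_non)
    return ExpressionContrast(fc={g: float(v) for g, v in fc.items()})


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene id, remaining columns samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fold_change_table(path: str | Path) -> ExpressionContrast:
    """Precomputed two-column TSV (gene, log2fc), e.g. exported from DESeq."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = df.columns[0]
    return ExpressionContrast(fc={g: float(v) for g, v in df[col].items()})
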