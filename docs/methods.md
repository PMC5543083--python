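# Methods

`regcore` implements a network-to-signature workflow for signed regulatory
networks: mine signed feedback loops, rank them with a weighted
multi-objective function, merge the winners into a regulatory core, and
simulate the core as a three-layer logic model whose ordinal phenotype
output predicts driver-receptor signatures and effective in-silico
interventions. This note records the models, the defaults and why they were
chosen, and the limits of what the tests demonstrate.

## Networks and feedback loops

A regulatory network is a directed multigraph whose edges carry an effect in
{activation, inhibition, unknown}. Parallel edges between the same ordered
pair with *different* effects coexist (a pair of genes can both activate and
inhibit each other through different mechanisms); exact duplicates are
collapsed with a warning. Identifiers are case-sensitive HUGO-style symbols
and no identifier mapping is attempted.

Feedback loops are simple directed cycles, enumerated up to a configurable
length cap (default 3: longer loops are typically composed of shorter ones,
and enumeration cost grows combinatorially). Each loop is canonicalized by
rotating its node sequence to the lexicographically smallest start, and its
key includes the edge effects so that parallel edges of conflicting sign
yield distinct loops. Sign follows the product rule — positive for an even
number of inhibitory edges, negative for odd — and any unknown edge makes
the loop *neutral*. Self-loops (length 1) are enumerated but excluded from
ranking by default; whether they belong in a loop census is
convention-dependent, so the census reports counts per length and the filter
is explicit.

## The multi-objective loop score

Loop *i* under weighting scenario *j* scores

    S_ij = (w1j/2)·⟨ND⟩_i/max(ND) + (w1j/2)·⟨BC⟩_i/max(BC)
         + w2j·⟨DP⟩_i/max(DP) + w3j·⟨GP⟩_i/max(GP) + w4j·⟨|FC|⟩_i/max(|FC|)

with ⟨ND⟩ the mean node degree (in+out, multiplicity counted), ⟨BC⟩ the mean
directed, unnormalized betweenness, ⟨DP⟩ the count of members in the disease
pathway, ⟨GP⟩ the mean random-walk prioritization score, and ⟨|FC|⟩ the mean
absolute log2 fold-change. Maxima run over all loops under consideration, so
each term is self-normalizing to [0,1] and invariant to uniform rescaling of
any raw criterion; the topology weight w1 is split evenly between degree and
betweenness so structure does not dominate. A criterion whose maximum is 0
carries no information and contributes 0. Weights must be non-negative and
sum to 1 (tolerance 1e-9); the degenerate all-zero vector is accepted and
scores everything 0, which keeps "weights off" configurations expressible.

The 13 default scenarios are the 4 one-hot vectors, the 6 equal-weight
pairs, the uniform vector, and two mixed emphases (0.4 on topology, and 0.4
on fold-change, with 0.2 elsewhere). They span the coordinate directions and
the balanced center of the weight simplex, which is the point of scanning
scenarios at all: the function is intrinsically multi-objective and a single
weight choice would bias the selection. The set is fully overridable via a
YAML list of 4-vectors. Ranking ties break by score descending, then ⟨|FC|⟩
descending (the most context-specific criterion), then canonical key — so
selection is deterministic. Top-k per scenario (default k = 10) are pooled
into a non-redundant union keyed by canonical node-and-edge identity.

## Node criteria

*Pathway membership* is exact string match (after trimming) against a gene
set, e.g. a GMT entry for a cancer pathway; absent genes are simply false.

*Random walk with restart* runs on the undirected skeleton by default —
prioritization measures proximity to seed genes, not regulation direction —
with `p ← (1−r)·W·p + r·p0`, column-stochastic W, uniform restart vector
over the seeds, restart probability r = 0.7 and L1 tolerance 1e-10. These
are common RWR practice; both are configurable, as is a directed-walk mode.
A dangling column (isolated node) retains its mass in place rather than
being spread uniformly: uniform replacement would leak restart probability
to nodes the seeds cannot reach, and an unreachable node should score
exactly 0. Scores are renormalized to sum to 1 on exit. The default seed
list is the packaged, editable EMT marker file (`data/emt_markers.txt`).

*Expression contrast* is the plain per-gene `log2((mean_inv + pc)/(mean_non
+ pc))` between two sample groups, antisymmetric under group swap.
Dispersion modeling and significance testing are deliberately out of scope;
precomputed fold-change tables from any differential-expression tool are
accepted verbatim. Genes missing from the table contribute fc = 0 and are
flagged.

## Core assembly

Selected loops are merged by set union of nodes and edges
(phenotype-category nodes excluded — the phenotype lives in the logic
model's output layer). Disjoint sub-networks are reconnected by importing
*all* direct full-network edges whose endpoints lie in different weak
components, labeled as bridges; no minimal-set selection is attempted, since
every true edge enriches the logic model and minimality would add an
arbitrary choice. An optional fallback (off by default) joins component
pairs that lack a direct edge through length-2 paths, importing the
intermediate node; intermediate hops ignore edge orientation because the
target property is weak connectivity. Reconnection guarantees a merge for
any component pair within two skeleton hops; components further apart in
the full network stay separate — multi-hop path stitching is out of scope.
Assembly is idempotent, and the core is always a subgraph of the full
network united with the selected loops.

## Logic models

A model has three disjoint layers: clamped Boolean inputs (receptors plus
the driving transcription factor), Boolean regulatory nodes, and one
multi-valued output. Updates are synchronous and deterministic:
`X_i(t+1) = BF_i(X(t))` from an all-zero regulatory start (configurable),
inputs and perturbation clamps held fixed, until a fixed point or a
revisited state. Synchronous fixed points coincide with logical steady
states, which is what the workflow needs; cycles are reported as attractors
with per-state phenotype levels and an oscillatory flag, never silently
aggregated, because no aggregation rule would be principled. Cycle
detection is by state hashing; a repeat is guaranteed within 2^n steps.

Multi-valued logic is confined to the output node: the phenotype level is
the sum of three Boolean factor expressions over marker states, giving an
ordinal 0–3 scale, e.g. for the bladder model

    EMT = [(SMAD2/3/4 AND SNAI1) OR (ZEB1 AND TWIST1)] + (NOT CDH1) + FGFR1

Rule files use a BoolNet-style dialect (`targets, factors` table;
AND/OR/NOT or &,|,!; parentheses; identifiers may contain `/ - . : _` so
symbols like `SMAD2/3/4` and `miR-25` parse whole), with header lines for
the input layer and the output factors. The parser is a small recursive
descent with NOT > AND > OR precedence.

*Template rule derivation* from a core: a node is ON iff (OR over its
activators) AND NOT (dominance expression over its inhibitors). Dominant
inhibitors are those upregulated in the invasive contrast (fc > 0); two or
more combine with AND — repressors that are jointly upregulated are treated
as cooperating, the convention the CDH1 rule illustrates — a single one
stands alone, and with none dominant all inhibitors combine with OR.
Unknown-effect edges are ignored; a node with no regulators and no override
is an error. Override expressions replace template rules verbatim.

*Perturbations* clamp one or two regulatory nodes to 0 (knockout/silencing)
or 1 (constitutive activation). The scan enumerates the baseline, every
single, and every unordered pair in all mode combinations, sorted by
phenotype reduction.

## Packaged core models

The exact published regulatory-layer rules are not publicly available, so
the two shipped models are documented reconstructions, each living in a
single rule file (`data/bladder_model.txt`, `data/breast_model.txt`) that is
the sole source of truth — nothing is hard-coded in the engine. The
reconstructions were constrained to reproduce the published desk-scale
outcomes:

- the full input-output tables: 64 bladder vectors collapsing to eight
  classes of eight (EMT = number of active drivers among
  E2F1/TGFBR1/FGFR1; EGFR/CXCR1/RARA free), and 128 breast vectors
  collapsing to eight classes of sixteen (drivers E2F1/TGFBR2/EGFR; free
  HMMR/THRB/IL1R1/RARA);
- the fully invasive state EMT = 3 under joint driver activation;
- the published double perturbations: in bladder, ZEB1 knockout combined
  with SNAI1, TWIST1 or NFKB1 knockout or CDH1 activation, and SMAD2/3/4
  knockout combined with TWIST1 or NFKB1 knockout, all reduce EMT to 1; in
  breast, pairs among SRC/FN1/SNAI1/SNAI2 silencing and CDH1 activation
  reduce EMT to 1.

Both regulatory layers are acyclic, so every simulation reaches a unique
fixed point from the all-zero start in a handful of steps regardless of
clamps. The breast phenotype rule is not published; it reuses the additive
three-factor template with factor 1 over the mesenchymal markers present in
that core ((SNAI1 AND SNAI2) OR (FN1 AND SRC)), factor 2 = NOT CDH1, factor
3 = EGFR.

Two reconstruction limits are worth stating plainly. First, of the ten
published breast double perturbations, nine are reproduced; the pair {FN1
knockout, CDH1 activation} yields EMT 2 here. Recovering it requires
bidirectional coupling between the SNAI branch and the SRC/FN1 branch,
which under synchronous updates from an all-zero start either oscillates or
breaks rows of the input-output table; an acyclic layer that provably
reproduces the tables was preferred over a cyclic one that recovers the
tenth pair at the cost of spurious oscillations. Second, some single hub
knockouts (bladder ZEB1 or NFKB1; breast SRC, SNAI1 or SNAI2) already reach
EMT 1 in the reconstructions; only double-perturbation outcomes are
published, so this is unconstrained, but it means the reconstructions do
not exhibit a strict single-vs-double gap for every hub.

## Sweeps, equivalence classes, signatures

Input-space enumeration is exact up to 20 inputs (2^20 vectors); beyond
that the API refuses and advises sampling. An input is *free* iff toggling
it changes no outcome in any context — an exact full-sweep comparison, not
a sampled estimate, which is affordable at these input counts. Classes
group vectors by the influential-input states; class sizes are powers of
two and sum to 2^m. The driver signature is the influential set with the
direction of the unique maximal class; ties are reported as ties, and a
constant-output model yields an empty signature. Random control signatures
(default 30 subsets of 3 nodes, matching the published control procedure)
are drawn without replacement within subsets, pairwise distinct, and
reproducible from the seed; they are emitted as TSV for external cohort
tooling — survival and stage statistics are out of scope.

## Synthetic data

The generators emulate only what the workflow consumes. Random signed
digraphs: independent directed edges with probability `edge_prob` (default
0.08 on 30 nodes), inhibition fraction 0.45 and unknown fraction 0.01 —
echoing the roughly balanced positive/negative loop composition and rare
neutral loops of curated cancer maps. Expression: log-normal abundances
with gene-specific baselines (log2 mean 6, sd 1 across genes), group shifts
planted in log2 space, and replicate noise of 0.25 log2 units (technical
replicates of cell lines), 20 samples per group; a planted 2.0 log2
fold-change is then recovered within ±0.2. These tables have no count
overdispersion, library-size variation, batch structure or correlated
genes, so passing tests show the contrast arithmetic and the pipeline
plumbing are correct on clean data — not that the workflow is robust to
real RNA-seq noise.

## Numerical and degenerate-input conventions

- Betweenness is directed and unnormalized; normalization happens only
  inside the motif score via division by the per-criterion maximum.
- Whole-network distance statistics (diameter, radius, characteristic path
  length) are computed over directed reachable pairs only, and the summary
  carries a strong-connectivity flag; a single isolated node has diameter 0.
- RWR convergence is L1 < 1e-10 with a closed-form linear solve as the
  independent cross-check (agreement within 1e-8 on 20-node graphs).
- The pipeline derives a fallback phenotype rule when none is supplied: the
  three regulatory nodes with the largest |fc| (ties by name) become
  additive factors. It is a placeholder for exploratory runs on synthetic
  cores, not a biological claim.
- Pipeline runs are deterministic under a fixed seed and config, including
  the summary file bytes.

## Problem sizes

The shipped test suite and the acceptance script run entirely at desk
scale: loop-enumeration cross-checks use 100 random digraphs with at most
12 nodes against an exhaustive pair/triple oracle, attractor cross-checks
use models with at most 10 regulatory nodes against the full 2^n transition
graph, RWR cross-checks use 20-node graphs, and the two packaged models
sweep 64 and 128 input vectors. These sizes make every oracle exact while
the whole suite completes in seconds.
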