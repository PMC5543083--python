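# Bladder-cancer core logic model (three layers).
#
# This rule set is a documented reconstruction of the invasive-bladder core:
# the input layer (E2F1 plus the receptors TGFBR1, FGFR1, EGFR, CXCR1, RARA),
# the Boolean regulatory layer, and the multi-valued EMT output
#   EMT = [(SMAD2/3/4 AND SNAI1) OR (ZEB1 AND TWIST1)] + (NOT CDH1) + FGFR1
# with levels 0 (no EMT) .. 3 (high EMT).  FGFR1 is not wired to any EMT
# marker and passes straight through to the output.  The regulatory rules are
# constrained to reproduce the published input-output table (EMT = number of
# active drivers among E2F1/TGFBR1/FGFR1; EGFR/CXCR1/RARA free) and the
# published double-perturbation outcomes; see docs/methods.md for the
# constraints behind every rule.
#
# Rule rationale, node by node:
#   NFKB1      survival hub collecting receptor signaling; any active input
#              except FGFR1 switches it on.
#   ZEB1       E2F1 target requiring NF-kB support.
#   TWIST1     direct E2F1 target.
#   SMAD2/3/4  activated by TGFBR1 signaling.
#   MDM2       E2F1 target destabilizing SNAI1, kept off while ZEB1 is active.
#   SNAI1      TGFBR1 target degraded when MDM2 accumulates.
#   CDH1       repressed only when its dominant repressors SNAI1 and TWIST1
#              cooperate (both upregulated in the invasive cell line).
inputs: E2F1, TGFBR1, FGFR1, EGFR, CXCR1, RARA
output: EMT
factor1: (SMAD2/3/4 AND SNAI1) OR (ZEB1 AND TWIST1)
factor2: NOT CDH1
factor3: FGFR1
targets, factors
NFKB1, E2F1 OR TGFBR1 OR EGFR OR CXCR1 OR RARA
ZEB1, E2F1 AND NFKB1
TWIST1, E2F1
SMAD2/3/4, TGFBR1
MDM2, E2F1 AND NOT ZEB1
SNAI1, TGFBR1 AND NOT MDM2
CDH1, NOT (SNAI1 AND TWIST1)
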