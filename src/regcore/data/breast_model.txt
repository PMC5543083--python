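# Breast-cancer core logic model (three layers).
#
# Documented reconstruction of the invasive-breast core: input layer E2F1
# plus the receptors TGFBR2, EGFR, HMMR, THRB, IL1R1, RARA; Boolean
# regulatory layer; multi-valued EMT output built from the same additive
# three-factor template as the bladder model, over the mesenchymal markers
# present in this core:
#   EMT = [(SNAI1 AND SNAI2) OR (FN1 AND SRC)] + (NOT CDH1) + EGFR
# EGFR passes straight through to the output.  The rules are constrained to
# reproduce the published input-output table (EMT = number of active drivers
# among E2F1/TGFBR2/EGFR; HMMR/THRB/IL1R1/RARA free) and the published
# double-perturbation outcomes; see docs/methods.md, including the one
# printed combination this reconstruction does not recover.
#
# Rule rationale, node by node:
#   SRC      direct E2F1 effector.
#   GSK3B    anti-EMT kinase, kept inactive by SRC signaling; with SRC gone
#            (under E2F1) it accumulates and destabilizes the SNAIs.
#   SNAI1/2  TGFBR2 targets degraded by active GSK3B.
#   FN1      SRC-driven matrix program; under TGF-beta signaling it
#            additionally requires the cooperating SNAI factors.
#   CDH1     repressed only by the joint action of SNAI1, SNAI2 and SRC.
#   TRAF1    survival adapter downstream of IL1R1 and HMMR.
#   MYC      induced by the hormone receptors THRB and RARA.
#   BIRC2/3  anti-apoptotic NF-kB/TRAF1 targets.
inputs: E2F1, TGFBR2, EGFR, HMMR, THRB, IL1R1, RARA
output: EMT
factor1: (SNAI1 AND SNAI2) OR (FN1 AND SRC)
factor2: NOT CDH1
factor3: EGFR
targets, factors
SRC, E2F1
GSK3B, E2F1 AND NOT SRC
SNAI1, TGFBR2 AND NOT GSK3B
SNAI2, TGFBR2 AND NOT GSK3B
FN1, SRC AND ((SNAI1 AND SNAI2) OR NOT TGFBR2)
CDH1, NOT (SNAI1 AND SNAI2 AND SRC)
TRAF1, IL1R1 OR HMMR
MYC, THRB OR RARA
BIRC2/3, TRAF1
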