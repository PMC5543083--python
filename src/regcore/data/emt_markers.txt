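# Epithelial-mesenchymal transition marker genes used as default seeds for
# random-walk gene prioritization.  Edit freely: one HUGO symbol per line,
# '#' starts a comment.  Epithelial and mesenchymal markers of the canonical
# EMT program (E-cadherin axis, EMT transcription factors, mesenchymal
# cytoskeleton/matrix genes).
CDH1
CDH2
VIM
FN1
SNAI1
SNAI2
ZEB1
ZEB2
TWIST1
TWIST2
MMP2
MMP9
ACTA2
CLDN1
OCLN
DSP
CTNNB1
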