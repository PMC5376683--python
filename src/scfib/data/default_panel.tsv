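gene_symbol	gene_group	aliases
CDH1	epithelial
EPCAM	epithelial
KRT18	epithelial
ACTA2	fibroblast	SMAa
COL1A1	fibroblast
TNC	fibroblast
FN1	fibroblast
FAP	fibroblast
S100A4	fibroblast	FSP1
MMP2	fibroblast
LOX	fibroblast
LOXL2	fibroblast
VIM	fibroblast
CD44	fibroblast
CAV1	fibroblast
CXCL12	chemokine_soluble	SDF1
PDGFA	chemokine_soluble
VEGFA	chemokine_soluble
HGF	chemokine_soluble
CCL5	chemokine_soluble	RANTES
CCL2	chemokine_soluble
IL6	chemokine_soluble
FGF2	chemokine_soluble
SNAI1	transcription_factor
SNAI2	transcription_factor
TWIST1	transcription_factor
ZEB1	transcription_factor
HIF1A	transcription_factor
CCNA2	proliferation
MKI67	proliferation
CCND1	proliferation
CDKN1A	proliferation	p21
ALDH1A3	bcsc
ALDH1A1	bcsc
CD24	bcsc
PROM1	bcsc	CD133
ITGA6	bcsc
POU5F1	pluripotency	OCT4
SOX2	pluripotency
NANOG	pluripotency
KLF4	pluripotency
CDH2	emt
GAPDH	reference
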