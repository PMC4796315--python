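gene_symbol	n_sp_lncRNAs
ARID2	7
BCL2	4
CBL	3
CCND1	1
CDC73	4
CYLD	6
DNMT3A	1
FAM123B	6
GATA2	1
KLF4	2
MLL2	13
PDGFRA	9
PIK3R1	7
PTEN	12
RUNX1	3
SMAD4	8
TET2	9
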