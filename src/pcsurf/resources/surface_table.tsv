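gene	is_surface	cd_alias
TNFRSF17	True	BCMA
SDC1	True	CD138
CD63	True	CD63
FCRL5	True	FCRH5
CD38	True	CD38
SLAMF7	True	CS1/CD319
TNFRSF13B	True	TACI/CD267
CD59	True	CD59
BST2	True	CD317
BSG	True	CD147
SLC44A1	True	CD92/CTL1
FCGR2B	True	CD32B
CD79B	True	CD79b
CD320	True	CD320
ICAM3	True	CD50
CD19	True	CD19
MS4A1	True	CD20
CD3D	True	CD3
CD3E	True	CD3
CD4	True	CD4
CD8A	True	CD8
NCAM1	True	CD56
CD14	True	CD14
ITGAM	True	CD11b
FCGR3A	True	CD16
CD33	True	CD33
CD34	True	CD34
IL3RA	True	CD123
IL6R	True	CD126
FGFR3	True	FGFR3
ITGB1	True	CD29
CD27	True	CD27
CD28	True	CD28
PDCD1	True	CD279
CD274	True	CD274
LAMP1	True	CD107a
THY1	True	CD90
KIT	True	CD117
MZB1	False
XBP1	False
JCHAIN	False
PRDM1	False
DERL3	False
IRF4	False
MKI67	False
CCND1	False
CCND2	False
CCND3	False
MAF	False
MAFB	False
MCL1	False
TP53	False
MYC	False
GAPDH	False
ACTB	False
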