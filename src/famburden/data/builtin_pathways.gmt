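hla_adaptive_immune	HLA class I/II and TAP antigen-presentation genes	HLA-A	HLA-B	HLA-C	HLA-DQA1	HLA-DQB1	HLA-DRB1	HLA-DPB1	TAP1	TAP2
collagen_biosynthesis	Fibrillar/network collagens and post-translational modification enzymes	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL11A1	COL11A2	COL17A1	COL18A1	PLOD1	PLOD2	PLOD3	SERPINH1
mitochondrial_respiratory	Mitochondrially encoded OXPHOS subunits	MT-ND1	MT-ND2	MT-ND3	MT-ND4	MT-ND4L	MT-ND5	MT-ND6	MT-CYB	MT-CO1	MT-CO2	MT-CO3	MT-ATP6	MT-ATP8
structural_cytoskeletal	Cytoskeletal and extracellular-matrix structural proteins	SYNE1	SYNE2	OBSCN	NEB	DMD	TTN	FLG	FLG-AS1	KRT74	KRT5	HSPG2	LAMA2	FLNC
protocadherin	Protocadherin gamma cluster	PCDHGA1	PCDHGA2	PCDHGA3	PCDHGA4	PCDHGA5	PCDHGA6	PCDHGA7	PCDHGA8	PCDHGA9	PCDHGA10	PCDHGA11	PCDHGA12	PCDHGB1	PCDHGB2	PCDHGB3	PCDHGB4	PCDHGB5	PCDHGB6	PCDHGB7
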