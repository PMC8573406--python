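Activated_B_cell	synthetic_standin	CD19	MS4A1	CD79A	CD79B	CD86
Activated_CD4_T_cell	synthetic_standin	CD4	IL2RA	CD69	ICOS	CD28
Activated_CD8_T_cell	synthetic_standin	CD8A	CD8B	GZMB	PRF1	IFNG
Activated_dendritic_cell	synthetic_standin	CD83	CCR7	LAMP3	CD80	CD40
CD56bright_natural_killer_cell	synthetic_standin	NCAM1	XCL1	XCL2	KLRC1	GZMK
CD56dim_natural_killer_cell	synthetic_standin	FCGR3A	KIR2DL1	KIR2DL3	GZMB	PRF1
Central_memory_CD4_T_cell	synthetic_standin	CD4	CCR7	SELL	IL7R	TCF7
Central_memory_CD8_T_cell	synthetic_standin	CD8A	CCR7	SELL	IL7R	BCL2
Effector_memory_CD4_T_cell	synthetic_standin	CD4	CCR5	GZMK	KLRG1	CXCR3
Effector_memory_CD8_T_cell	synthetic_standin	CD8A	GZMK	KLRG1	CX3CR1	EOMES
Eosinophil	synthetic_standin	SIGLEC8	CCR3	IL5RA	EPX	PRG2
Gamma_delta_T_cell	synthetic_standin	TRDC	TRGC1	TRGC2	KLRC1	NKG7
Immature_B_cell	synthetic_standin	CD19	CD38	MME	VPREB1	IGLL1
Immature_dendritic_cell	synthetic_standin	CD1C	CD1A	FCER1A	ITGAX	CLEC10A
Macrophage	synthetic_standin	CD68	CD163	MRC1	CSF1R	MSR1
Mast_cell	synthetic_standin	TPSAB1	TPSB2	CPA3	MS4A2	KIT
MDSC	synthetic_standin	ITGAM	ARG1	S100A8	S100A9	CD33
Memory_B_cell	synthetic_standin	CD19	CD27	MS4A1	TNFRSF13B	CD40
Monocyte	synthetic_standin	CD14	FCN1	LYZ	VCAN	S100A12
Natural_killer_cell	synthetic_standin	NCR1	KLRD1	NKG7	GNLY	KLRF1
Natural_killer_T_cell	synthetic_standin	CD3E	NCAM1	KLRB1	ZBTB16	IL2RB
Neutrophil	synthetic_standin	FCGR3B	CSF3R	CXCR2	FUT4	MPO
Plasmacytoid_dendritic_cell	synthetic_standin	CLEC4C	IL3RA	LILRA4	IRF7	TCF4
Regulatory_T_cell	synthetic_standin	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18
T_follicular_helper_cell	synthetic_standin	CXCR5	BCL6	ICOS	PDCD1	IL21
Type_1_T_helper_cell	synthetic_standin	TBX21	IFNG	CXCR3	IL12RB2	STAT4
Type_17_T_helper_cell	synthetic_standin	RORC	IL17A	IL23R	CCR6	STAT3
Type_2_T_helper_cell	synthetic_standin	GATA3	IL4	IL5	IL13	CCR4
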