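B_lineage	TLS signature: B-lineage markers	CD79A	CD79B	CD19	MS4A1	BANK1	CR2	FCRL2	IGKC	PAX5	CD22
T_cells	T cell markers	CD3D	CD3E	CD3G	CD2	CD5	CD6	CD28	TRAT1
Myeloid_dendritic_cells	Myeloid DC markers	CD1A	CD1B	CD1E	CLEC10A	CLIC2	WFDC21P
Monocytic_lineage	Monocyte/macrophage markers	CD14	CSF1R	CD163	MSR1	ADAP2
NK_cells	Natural killer markers	KIR2DL1	KIR2DL3	NCR1	PRF1	GNLY	KLRD1
Neutrophils	Neutrophil markers	FCGR3B	CSF3R	CEACAM3	FPR1	CXCR2
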