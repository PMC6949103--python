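cell_type	gene
B cells	CD19
B cells	MS4A1
B cells	CD79A
B cells	CD79B
CD4+ T cells	CD4
CD4+ T cells	IL7R
CD4+ T cells	CD40LG
CD8+ T cells	CD8A
CD8+ T cells	CD8B
CD8+ T cells	GZMK
Neutrophils	FCGR3B
Neutrophils	CSF3R
Neutrophils	S100A8
Neutrophils	FPR1
Macrophages	CD68
Macrophages	CD163
Macrophages	CSF1R
Macrophages	MRC1
Dendritic cells	ITGAX
Dendritic cells	CD1C
Dendritic cells	CLEC4C
Dendritic cells	NRP1
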