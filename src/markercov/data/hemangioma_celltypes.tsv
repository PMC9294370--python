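cell_type	n_cells	marker_genes	uicc
Fibroblast	2033	C3,CHRDL1,MFAP4,OGN,PDGFRL	0.27
MSC	610	UNC5B,ADAM12,PYCR1,ALDH1L2,CREB3L1	0.31
SMC	881	SYNPO2,RGS5,CPE,PDE5A,EDNRA	0.26
EC1	1032	PLVAP,APLNR,RAMP3,CLDN5,RBP7	0.29
EC2	2273	TFF3,MMRN1,EFNB2,RAPGEF5,TIE1	0.26
LEC	38	CCL21,MPP7,PROX1,TBX1,LYVE1	0.37
CD4+TC	596	CD3E,CD3G,CD3D,IL7R,PIK3IP1	0.22
CD8+TC	307	GZMA,CCL5,KLRD1,GZMM,NKG7	0.29
NKC	201	XCL2,TRDC,GNLY,TNFRSF18,KLRB1	0.27
BC	119	MS4A1,CD79A,TNFRSF13C,BIRC3,CD37	0.25
Mast	137	CMA1,MS4A2,SLC18A2,TPSAB1,CPA3	0.47
mDC	266	CD1C,FCER1A,IL1R2,HLA-DQA2,CLEC10A	0.28
pDC	36	SHD,LILRA4,SCT,CLEC4C,LRRC26	0.14
CLEC9A+DC	47	CLEC9A,XCR1,FLT3,SLAMF7,S100B	0.30
m1Maph	922	OLR1,EREG,BCL2A1,SLC11A1,NLRP3	0.32
m2Maph	1286	FOLR2,LILRB5,C1QC,MS4A4A,C1QB	0.46
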