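gene	avg_in	lfcio	pct_in	pct_out	ratio
UNC5B	0.60	3.86	63.30	2.70	23.44
ADAM12	1.15	2.55	75.60	6.00	12.60
PYCR1	0.75	2.98	71.80	5.80	12.38
ALDH1L2	0.44	2.59	60.20	5.00	12.04
CREB3L1	1.10	3.33	79.00	6.70	11.79
UCHL1	1.22	3.33	65.90	6.30	10.46
PHGDH	0.60	2.69	66.10	6.40	10.33
GPC1	1.02	2.88	78.70	9.10	8.65
SCARF2	1.17	2.68	84.90	10.00	8.49
ENPP1	1.66	3.14	69.20	8.30	8.34
NCS1	0.56	2.43	64.10	7.70	8.32
COL5A3	3.42	3.40	94.60	11.90	7.95
SLIT2	0.59	2.14	62.80	8.10	7.75
PFN2	0.91	2.54	77.70	10.10	7.69
TNFAIP6	2.99	3.28	81.80	11.20	7.30
DCBLD2	2.35	3.63	88.70	12.70	6.98
TNC	2.55	2.32	84.60	12.20	6.93
EDIL3	2.07	2.42	84.90	12.50	6.79
RP11-14N7.2	0.82	2.22	73.80	10.90	6.77
CHPF	1.20	2.00	83.40	12.40	6.73
P4HA2	2.02	3.02	84.40	12.60	6.70
LOXL1	1.66	2.26	81.60	12.30	6.63
TWIST1	1.20	2.19	80.30	12.20	6.58
SNAI2	1.60	2.59	81.50	12.40	6.57
EMILIN1	1.78	2.56	90.00	14.30	6.29
TNFRSF12A	2.79	3.41	70.20	11.30	6.21
CCDC102B	0.93	2.01	65.70	10.80	6.08
PHLDA2	2.07	2.91	72.00	12.20	5.90
C11orf24	0.86	2.27	75.10	12.90	5.82
KDELR3	1.84	2.43	87.70	15.30	5.73
PAPSS2	0.99	2.09	78.00	14.10	5.53
CYGB	1.62	2.22	69.80	13.10	5.33
LOX	3.12	2.41	89.00	16.80	5.30
CERCAM	2.25	2.09	93.10	18.00	5.17
C12orf75	3.30	3.02	81.80	16.90	4.84
CLEC11A	3.15	2.47	96.60	20.50	4.71
PLOD2	1.55	2.16	80.20	17.70	4.53
UGDH	1.20	2.16	78.50	17.40	4.51
TUBB2A	1.47	2.08	75.20	17.80	4.22
LOXL2	4.27	2.78	91.50	22.10	4.14
BMP1	1.91	2.21	89.00	21.50	4.14
GPX8	2.10	2.01	91.60	23.00	3.98
RCN3	5.04	2.97	96.10	24.20	3.97
SULF1	2.78	2.17	85.90	22.60	3.80
COL5A1	8.90	2.50	99.30	27.60	3.60
FKBP10	2.75	2.20	95.20	26.90	3.54
TPM2	10.25	2.41	98.70	28.20	3.50
LRRC59	2.04	2.14	84.40	24.90	3.39
CKAP4	4.19	2.48	94.90	29.90	3.17
UACA	3.83	2.22	91.60	31.50	2.91
COL5A2	13.55	2.36	99.70	35.40	2.82
SERPINH1	5.16	2.12	98.00	37.30	2.63
COL6A3	39.17	2.61	99.30	39.30	2.53
PRDX4	4.79	2.08	96.40	40.10	2.40
POSTN	23.30	2.29	86.20	36.80	2.34
TPM1	8.72	2.13	97.20	42.20	2.30
ID3	9.07	2.04	93.30	43.60	2.14
CALU	7.22	2.03	98.70	49.20	2.01
COL6A1	31.81	2.41	99.80	51.60	1.93
MYDGF	6.20	2.07	96.10	50.10	1.92
FN1	52.12	2.27	99.80	67.00	1.49
COL3A1	133.81	2.02	100.00	68.30	1.46
COL1A1	210.95	2.64	100.00	69.00	1.45
COL1A2	128.04	2.07	100.00	74.10	1.35
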