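probe_id	gene_id	accession	fc_abs	p	regulation	C1	C2	C3	N1	N2	N3	chrom
A_33_P3368985	ANKRD30A	NM_052997	155.29	0.03	down	8.00	1.60	3.85	12.90	9.32	13.06	chr10
A_23_P8820	FABP4	NM_001442	97.90	0.01	down	2.76	1.39	2.12	7.61	7.36	11.14	chr8
A_23_P161940	SCGB2A2	NM_002411	92.77	0.03	down	2.51	1.48	2.36	11.72	4.99	9.24	chr11
A_23_P218047	KRT5	NM_000424	63.47	0.03	down	9.25	3.97	5.83	12.93	10.68	13.41	chr12
A_23_P12533	ANKRD30A	NM_052997	60.17	0.04	down	6.66	1.79	2.69	10.86	7.00	11.01	chr10
A_33_P3320683			51.36	0.03	down	7.43	2.81	4.11	11.59	8.11	11.70	chr10
A_21_P0010304	ANKRD30A	NM_052997	43.24	0.04	down	6.61	1.50	3.86	10.56	7.24	10.47	chr10
A_23_P111583	CD36	NM_001001547	28.94	0.01	down	6.49	5.52	5.98	10.87	9.35	12.33	chr7
A_23_P127781	SCGB1D1	NM_006552	28.85	0.03	down	1.81	2.28	2.15	9.00	4.21	7.57	chr11
A_24_P273756	TP63	NM_003722	27.89	0.05	down	6.25	1.86	3.92	10.11	6.49	9.83	chr3
A_23_P206920	MYH11	NM_001040114	27.31	0.04	down	7.89	3.40	7.85	11.87	9.87	11.72	chr16
A_24_P70183	MYH11	NM_001040113	26.71	0.05	down	7.85	3.31	7.82	11.80	9.61	11.78	chr16
A_24_P260101	MME	NM_007289	25.46	0.02	down	4.02	3.17	1.37	8.30	5.44	8.83	chr3
A_33_P3319486			24.18	0.01	down	3.11	2.40	1.67	7.13	5.48	8.35	chr7
A_24_P123408	ABLIM3	NM_014945	24.12	0.03	down	6.01	2.24	4.15	9.43	6.99	9.75	chr5
A_23_P385861	CDCA2	NM_152562	22.83	0.03	up	9.83	6.92	7.36	2.58	5.42	2.57	chr8
A_23_P323751	FAM83D	NM_030919	22.31	0.03	up	8.36	5.87	7.33	1.44	5.10	1.59	chr20
A_23_P356684	ANLN	NM_018685	21.49	0.02	up	8.91	7.34	7.56	2.05	5.78	2.70	chr7
A_24_P305050	CD300LG	NM_145273	20.28	0.01	down	3.15	4.37	2.88	8.26	6.14	9.03	chr17
A_23_P403284	OTX1	NM_014562	19.52	0.00	up	8.08	8.74	9.78	3.96	5.42	4.35	chr2
A_23_P45185	FIGF	NM_004469	19.18	0.02	down	1.99	2.55	1.51	6.84	4.25	7.75	chrX
A_23_P77493	TUBB3	NM_006086	18.79	0.03	up	10.62	8.63	6.45	4.57	5.16	3.27	chr16
A_23_P169437	LCN2	NM_005564	18.32	0.01	up	8.88	9.44	9.87	6.25	3.62	5.74	chr9
A_24_P413884	CENPA	NM_001809	17.22	0.02	up	7.19	6.01	6.33	1.32	4.51	1.38	chr2
A_23_P315364	CXCL2	NM_002089	16.18	0.03	down	4.47	3.95	2.05	8.93	5.52	8.07	chr4
A_23_P94422	MELK	NM_014791	16.16	0.04	up	9.81	8.94	9.20	3.86	7.84	4.20	chr9
A_24_P844984	PIGR	NM_002644	16.09	0.02	down	4.57	6.24	4.60	10.07	7.47	9.90	chr1
A_23_P218369	CCL14	NM_032963	16.09	0.01	down	5.07	2.38	4.81	7.36	8.10	8.82	chr17
A_24_P331150	CYP4F22	NM_173483	16.00	0.05	down	2.84	2.41	2.39	6.84	3.94	8.87	chr19
A_23_P81280	BTNL9	NM_152547	15.91	0.02	down	3.23	3.72	4.91	7.64	6.66	9.54	chr5
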