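probe_id	fc_abs	p	regulation	C1	C2	C3	N1	N2	N3	seq_id	chrom
XR_250621.1	291.27	0.03	down	9.31	1.54	3.97	14.14	10.96	14.27	humanseq85285
NONHSAT012762	164.35	0.04	down	8.00	1.56	1.72	12.20	8.81	12.35	humanseq57970	chr10
TCONS_l2_00002973	144.14	0.04	down	8.09	1.33	2.98	12.59	8.67	12.65	humanseq9097	chr10
NONHSAG005629	135.22	0.04	down	8.22	1.49	3.54	12.67	9.20	12.62	humanseq57206	chr10
NONHSAG050621	133.56	0.01	down	4.09	1.29	2.81	8.88	8.32	12.17	humanseq52435	chr8
NONHSAT012761	128.01	0.04	down	7.94	1.24	3.46	12.45	8.49	12.70	humanseq57969	chr10
NONHSAT127452	113.99	0.01	down	2.81	1.66	1.40	7.76	7.49	11.12	humanseq52434	chr8
XR_252733.1	105.54	0.03	down	7.33	1.50	2.51	11.57	8.26	11.68	humanseq83671
TCONS_l2_00002976	99.20	0.04	down	8.08	1.55	3.87	12.28	8.59	12.53	humanseq9047	chr10
NONHSAT012773	90.54	0.04	down	6.95	1.74	1.87	11.13	7.47	11.46	humanseq57973	chr10
TCONS_l2_00002971	62.00	0.04	down	7.64	3.46	2.77	11.67	8.00	12.06	humanseq9095	chr10
NONHSAT121750	57.36	0.00	down	2.38	1.45	1.53	7.62	6.19	9.09	humanseq49910	chr7
NR_104061.1	55.50	0.04	down	7.57	3.66	2.70	11.53	8.19	11.59	humanseq86747	chr10
NONHSAT012774	54.24	0.03	down	6.95	4.22	2.64	11.26	8.11	11.72	humanseq57974	chr10
TCONS_l2_00002977	52.98	0.04	down	5.64	1.44	1.34	9.75	5.82	10.02	humanseq9048	chr10
TCONS_l2_00002974	52.00	0.04	down	7.59	4.23	2.76	11.56	8.29	11.83	humanseq9098	chr10
TCONS_l2_00002972	41.39	0.04	down	6.35	2.56	2.81	10.39	6.79	10.65	humanseq9096	chr10
NR_026916.1	35.88	0.04	down	6.91	2.50	4.67	11.04	7.57	10.97	humanseq88505
TCONS_l2_00002970	35.17	0.04	down	5.42	1.80	4.24	9.97	6.42	10.49	humanseq9094	chr10
NONHSAT016222	33.04	0.03	down	5.97	2.48	3.51	10.08	6.89	10.12	humanseq58945	chr10
NONHSAT136770	31.09	0.02	down	3.00	2.76	1.23	7.78	5.03	9.07	humanseq55779	chrX
NONHSAT004026	27.10	0.02	down	5.15	2.65	1.85	8.86	6.53	8.55	humanseq30344	chr1
NONHSAG048085	26.13	0.01	down	6.41	5.58	5.77	10.52	9.15	12.22	humanseq49906	chr7
NONHSAT009093	24.41	0.02	down	4.69	6.61	4.89	11.01	8.08	10.93	humanseq32309	chr1
NONHSAT125629	23.95	0.03	up	9.95	6.97	7.45	2.17	5.68	2.77	humanseq51739	chr8
NONHSAT066780	23.54	0.02	down	4.72	4.32	5.21	11.14	7.19	9.59	humanseq77727	chr19
NONHSAT012776	23.09	0.01	down	1.86	1.35	2.54	7.45	4.67	7.21	humanseq57975	chr10
XR_133419.2	22.26	0.01	down	1.35	2.01	1.30	6.48	4.06	7.56	humanseq84668
NONHSAT121746	21.61	0.03	down	1.30	3.18	2.19	6.98	4.35	8.64	humanseq49907	chr7
NONHSAT098133	20.15	0.00	down	1.46	1.46	1.35	6.44	4.45	6.37	humanseq41971	chr4
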