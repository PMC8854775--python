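gene_name	start	log2_fc_monosomy	linear_fc_monosomy	p_adj_monosomy	log2_fc_trisomy	linear_fc_trisomy	p_adj_trisomy
MRPL39	25585656	-0.59	0.67	<0.001	0.63	1.55	<0.001
JAM2	25639258	-0.42	0.75	0.011	0.36	1.29	0.017
CYYR1	26466209	-0.80	0.57	0.043	0.43	1.34	<0.001
ADAMTS1	26835755	-1.02	0.49	0.002	1.02	2.03	<0.001
SCAF4	31671000	-0.47	0.72	<0.001	0.50	1.41	<0.001
ETS2	38805183	-0.90	0.54	0.003	0.94	1.92	<0.001
BACE2	41167801	-2.88	0.14	<0.001	0.78	1.72	<0.001
PDE9A	42653621	-2.38	0.19	<0.001	0.87	1.83	<0.001
WDR4	42843094	-1.50	0.35	<0.001	1.04	2.06	<0.001
CSTB	43772511	-0.67	0.63	<0.001	0.49	1.41	0.006
RRP1	43789513	-0.48	0.72	0.007	0.92	1.89	<0.001
LRRC3	44455510	-1.28	0.41	<0.001	1.09	2.12	<0.001
UBE2G2	44768580	-1.58	0.34	<0.001	1.09	2.13	<0.001
SUMO3	44805617	-1.56	0.34	<0.001	1.30	2.46	<0.001
PTTG1IP	44849585	-1.13	0.46	<0.001	0.63	1.54	<0.001
FAM207A	44940012	-1.37	0.39	0.001	0.56	1.47	0.013
ADARB1	45073853	-1.73	0.30	<0.001	1.22	2.33	<0.001
LSS	46188141	-1.16	0.45	<0.001	0.66	1.58	0.024
MCM3AP	46235133	-0.91	0.53	<0.001	0.48	1.40	0.044
YBEY	46286342	-0.91	0.53	<0.001	0.91	1.88	<0.001
C21orf58	46300181	-1.04	0.49	<0.001	0.75	1.69	<0.001
PCNT	46324141	-1.41	0.38	<0.001	0.77	1.71	<0.001
PRMT2	46635595	-0.76	0.59	<0.001	1.15	2.22	<0.001
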