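# HMW glutenin subunit spots: identification and normalized volume (% of gel total, mean of 3 replicates)
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T3	12	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	1.22	0.024	52	86336	5.7
T3	16	HMW-GS	Glu-A1	HMW-GS Ax2*	A	2	0.07	0.004	13	86336	5.7
T3	17	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	0.36	0.019	34	86336	5.7
T3	18	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	0.05	0.001	7	86336	5.7
T3	19	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	0.14	0.005	10	86336	5.7
T3	23	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	0.40	0.006	26	86336	5.7
T3	24	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	0.13	0.006	22	86336	5.7
T3	28	HMW-GS	Glu-A1	HMW-GS Ax2*	A	1	0.03	0.004	8	86336	5.7
T3	20	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	1.79	0.053	56	82527	8.4
T3	21	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	2.28	0.063	57	82527	8.4
T3	25	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	0.12	0.026	6	82527	8.4
T3	26	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	0.48	0.016	10	82527	8.4
T3	27	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	0.18	0.004	5	82527	8.4
T3	29	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	0.02	0.002	3	82527	8.4
T3	33	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	0.05	0.002	3	82527	8.4
T3	302	HMW-GS	Glu-B1	HMW-GS Bx7	B	1	0.10	0.009	3	82527	8.4
T3	40	HMW-GS	Glu-B1	HMW-GS By9	B	2	0.38	0.003	34	73518	8.4
T3	47	HMW-GS	Glu-B1	HMW-GS By9	B	1	0.05	0.002	10	73518	8.4
T3	52	HMW-GS	Glu-B1	HMW-GS By9	B	1	0.05	0.004	19	73518	8.4
T3	349	HMW-GS	Glu-B1	HMW-GS By9	B	1	0.11	0.016	27	73518	8.4
T3	350	HMW-GS	Glu-B1	HMW-GS By9	B	1	1.32	0.004	56	73518	8.4
T3	351	HMW-GS	Glu-B1	HMW-GS By9	B	2	0.15	0.017	45	73518	8.4
T3	358	HMW-GS	Glu-B1	HMW-GS By9	B	1	0.08	0.007	20	73518	8.4
T3	360	HMW-GS	Glu-B1	HMW-GS By9	B	1	0.14	0.021	48	73518	8.4
T3	3	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	2.37	0.020	50	87941	6.1
T3	5	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.70	0.043	45	87941	6.1
T3	7	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.16	0.007	3	87941	6.1
T3	10	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.06	0.004	19	87941	6.1
T3	14	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.05	0.007	16	87941	6.1
T3	36	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.07	0.006	4	87941	6.1
T3	138	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.21	0.024	4	87941	6.1
T3	307	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.08	0.028	21	87941	6.1
T3	538	HMW-GS	Glu-D1	HMW-GS Dx5	D	1	0.05	0.002	3	87941	6.1
T3	42	HMW-GS	Glu-D1	HMW-GS Dy10	D	2	2.32	0.051	57	67475	7.0
T3	48	HMW-GS	Glu-D1	HMW-GS Dy10	D	1	0.21	0.032	57	67475	7.0
T3	51	HMW-GS	Glu-D1	HMW-GS Dy10	D	2	0.17	0.014	57	67475	7.0
T3	333	HMW-GS	Glu-D1	HMW-GS Dy10	D	1	0.65	0.030	57	67475	7.0
T3	407	HMW-GS	Glu-D1	HMW-GS Dy10	D	1	0.07	0.019	57	67475	7.0
T3	424	HMW-GS	Glu-D1	HMW-GS Dy10	D	1	0.20	0.014	57	67475	7.0
T3	514	HMW-GS	Glu-D1	HMW-GS Dy10	D	1	0.07	0.010	57	67475	7.0
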