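# Omega-gliadin spots, grouped by locus-level type
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T6	60	omega-gliadin	omega-5 Gli-B3	Omega-gliadin omega-5 TC11_288652	B	1	1.39	0.126	14	50904	6.0
T6	63	omega-gliadin	omega-5 Gli-B3	Omega-gliadin omega-5 TC11_288652	B	1	0.19	0.025	13	50904	6.0
T6	69	omega-gliadin	omega-5 Gli-B3	Omega-gliadin omega-5 type	B	1	0.18	0.006	inc	inc	inc
T6	71	omega-gliadin	omega-5 Gli-B3	Omega-gliadin omega-5 TC11_288652	B	1	1.27	0.171	26	50904	6.0
T6	73	omega-gliadin	omega-5 Gli-B3	Omega-gliadin omega-5 type	B	1	0.28	0.028	inc	inc	inc
T6	74	omega-gliadin	omega-5 Gli-B3	Omega-gliadin omega-5 TC11_288652	B	1	1.77	0.235	30	50904	6.0
T6	476	omega-gliadin	omega-1/2 Gli-D3	Omega-gliadin Gli-D3 type	D	1	2.07	0.136	inc	inc	inc
T6	477	omega-gliadin	omega-1/2 Gli-D3	Omega-gliadin Bu-D1/AAT74547	D	3	0.99	0.087	23	43525	6.0
T6	107	omega-gliadin	1D-Cys	Omega-gliadin TC262770	D	1	0.12	0.015	8	41811	5.0
T6	113	omega-gliadin	1D-Cys	Omega-gliadin TC262770	D	2	0.50	0.012	46	41811	5.0
T6	115	omega-gliadin	1D-Cys	Omega-gliadin TC262770	D	2	0.47	0.065	34	41811	5.0
T6	116	omega-gliadin	1D-Cys	Omega-gliadin TC262770	D	1	0.16	0.024	8	41811	5.0
T6	130	omega-gliadin	omega-1/2 Gli-A3	Omega-secalin-like ACN96903	A	1	0.08	0.055	27	39492	7.0
T6	135	omega-gliadin	omega-1/2 Gli-A3	Omega-gliadin Bu-D5	A	1	0.56	0.055	inc	inc	inc
T6	391	omega-gliadin	omega-1/2 Gli-A3	Omega-gliadin Bu-D5	A	2	0.43	0.049	inc	inc	inc
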