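# LMW glutenin subunit spots, grouped by mature N-terminal type / locus
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T4	125	LMW-GS	QISQQQ-type	LMW-GS AAB48469	A	2	0.32	0.181	41	39417	8.5
T4	140	LMW-GS	QISQQQ-type	LMW-GS Bu-4/P10385	A	1	0.19	0.018	50	39130	8.9
T4	141	LMW-GS	QISQQQ-type	LMW-GS Bu-4/P10385	A	1	1.10	0.031	51	39130	8.9
T4	141a	LMW-GS	QISQQQ-type	LMW-GS Bu-4/P10385	A	2	0.58	0.059	16	39130	8.9
T4	314	LMW-GS	QMENSHIP-type	LMW-GS Bu-2/12/13	B	2	1.35	0.163	44	38153	8.2
T4	317	LMW-GS	QMENSHIP-type	LMW-GS Bu-2/12/13	B	3	0.35	0.017	45	38153	8.2
T4	318	LMW-GS	QMENSHIP-type	LMW-GS Bu-2/12/13	B	3	0.34	0.046	33	38153	8.2
T4	322	LMW-GS	QMENSHIP-type	LMW-GS Bu-2/12/13	B	2	0.37	0.008	28	38153	8.2
T4	119	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	1	2.40	0.354	79	42589	8.5
T4	119a	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	2	0.69	0.256	62	42589	8.5
T4	120	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	1	0.78	0.112	61	42589	8.5
T4	131	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	1	0.72	0.047	48	42589	8.5
T4	132	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	1	0.10	0.008	39	42589	8.5
T4	161	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	3	<0.01	0.000	23	42589	8.5
T4	237	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	1	0.03	0.003	16	42589	8.5
T4	310	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	3	1.13	0.054	50	42589	8.5
T4	316	LMW-GS	QMENSHIP-type	LMW-GS Bu-3	B	3	0.21	0.033	36	42589	8.5
T4	167	LMW-GS	QMET-type	LMW-GS Bu-1	D	4	2.10	0.037	89	33008	8.7
T4	170	LMW-GS	QMET-type	LMW-GS Bu-1	D	3	0.33	0.021	66	33008	8.7
T4	173	LMW-GS	QMET-type	LMW-GS Bu-6	D	3	0.47	0.007	78	31901	8.9
T4	144	LMW-GS	QMET-type	LMW-GS Bu-7	D	1	1.52	0.040	50	37700	8.2
T4	145	LMW-GS	QMET-type	LMW-GS Bu-7	D	2	0.78	0.021	55	37700	8.2
T4	472	LMW-GS	QMET-type	LMW-GS Bu-7	D	3	0.17	0.071	48	37700	8.2
T4	343	LMW-GS	QMET-type	LMW-GS Bu-8	D	3	0.29	0.057	61	32175	7.7
T4	203	LMW-GS	QMET-type	LMW-GS Bu-11/AAT37861	D	2	<0.01	0.000	11	39788	8.5
T4	315	LMW-GS	QMET-type	LMW-GS Bu-11/AAT37861	D	2	0.27	0.027	52	39788	8.5
T4	153	LMW-GS	QMET-type	LMW-GS Bu-18/TC250064	D	1	0.26	0.030	49	37126	8.5
T4	155	LMW-GS	QMET-type	LMW-GS Bu-18/TC250064	D	2	0.47	0.012	50	37126	8.5
T4	319	LMW-GS	QMET-type	LMW-GS TC11_277270	D	2	0.67	0.038	55	39762	8.5
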