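# Alpha-gliadin spots (celiac column: epitope codes; 5 = 33-mer, 6 = p31-43, "-" = none detected)
# plus the gliadin mixed spots (no strict-majority predominant protein)
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T7	183	alpha-gliadin	Gli-A2	Alpha-gliadin Bu-5	A	3	1.23	0.076	76	30506	7.1	6
T7	344	alpha-gliadin	Gli-A2	Alpha-gliadin Bu-5	A	1	0.16	0.028	57	30506	7.1	6
T7	331	alpha-gliadin	Gli-A2	Alpha-gliadin Bu-14	A	2	0.28	0.041	15	29995	6.2	6
T7	190	alpha-gliadin	Gli-A2	Alpha-gliadin Bu-14	A	2	0.48	0.035	78	29995	6.2	6
T7	206	alpha-gliadin	Gli-A2	Alpha-gliadin Bu-14	A	3	0.15	0.077	29	29995	6.2	6
T7	546	alpha-gliadin	Gli-A2	Alpha-gliadin Bu-14	A	3	0.18	0.029	47	29995	6.2	6
T7	327	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-11	B	5	1.59	0.107	30	34599	6.5	4
T7	525	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-12	B	4	0.56	0.097	65	31541	7.0	-
T7	328	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-12	B	4	0.27	0.058	25	31541	7.0	-
T7	329	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-12	B	4	1.59	0.172	27	31541	7.0	-
T7	387	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-12	B	4	0.17	0.017	49	31541	7.0	-
T7	524	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-12	B	4	0.47	0.032	80	31541	7.0	-
T7	341	alpha-gliadin	Gli-B2	Alpha-gliadin Bu-23	B	3	3.29	0.154	59	33871	7.1	-
T7	342	alpha-gliadin	Gli-D2	Alpha-gliadin Bu-1	D	4	0.85	0.059	60	33412	7.8	1,2,3,4,5
T7	330	alpha-gliadin	Gli-D2	Alpha-gliadin Bu-2	D	6	2.66	0.148	52	30807	7.7	1,2,4
T7	338	alpha-gliadin	Gli-D2	Alpha-gliadin Bu-2	D	2	0.56	0.034	60	30808	7.7	1,2,4
T7	468	alpha-gliadin	Gli-D2	Alpha-gliadin Bu-3	D	4	1.66	0.119	71	33156	7.0	1,2,3,4,5
T7	467	alpha-gliadin	Gli-D2	Alpha-gliadin Bu-4	D	6	2.01	0.183	78	31462	6.6	1,2,3,4
T7	550	alpha-gliadin	Gli-D2	Alpha-gliadin Bu-10	D	4	1.31	0.127	75	31551	6.8	1,2,3
T7	124	alpha-gliadin	unknown	Alpha-gliadin Bu BQ807130		1	0.29	0.024	inc	inc	inc	inc
T7	177	alpha-gliadin	unknown	Alpha-gliadin Bu BQ806209		5	0.32	0.118	inc	inc	inc	inc
T7	420	alpha-gliadin	unknown	Alpha-gliadin Bu-27		3	0.34	0.055	55	34268	8.3	-
T7	334	mixed		3 gamma-gliadins, 1 alpha-gliadin		4	1.08	0.105	nd	nd	nd	nd
T7	389	mixed		1 alpha-gliadin, 1 other protein		2	0.14	0.009	nd	nd	nd	nd
T7	172	mixed		1 gamma-gliadin, 2 alpha-gliadins		3	1.21	0.100	nd	nd	nd	nd
T7	530	mixed		1 globulin, 1 alpha-gliadin		2	0.08	0.019	nd	nd	nd	nd
T7	195	mixed		1 farinin, 1 alpha-gliadin, 1 enzyme		3	0.05	0.018	nd	nd	nd	nd
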