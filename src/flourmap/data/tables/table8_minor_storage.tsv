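# Farinin, purinin, triticin, globulin and GSP/puroindoline spots
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T8	196	farinin		Farinin Bu-1 full length		1	0.04	0.007	15	29978	8.1
T8	385	farinin		Farinin Bu-1 C-terminus		1	0.07	0.013	13	18832	8.4
T8	386	farinin		Farinin Bu-1 C-terminus		1	0.14	0.030	24	18832	8.4
T8	193	farinin		Farinin Bu-2		2	0.28	0.052	38	30567	7.5
T8	207	farinin		Farinin Bu-2		1	0.04	0.037	25	30567	7.5
T8	549	farinin		Farinin Bu-2		1	<0.01	0.000	20	30567	7.5
T8	336	farinin		Farinin Bu-3		2	0.33	0.043	45	30883	7.9
T8	345	farinin		Farinin Bu-3		3	<0.01	0.000	34	30883	7.9
T8	542	purinin		Purinin Bu-1		3	0.07	0.007	24	20272	5.9
T8	543	purinin		Purinin Bu-1		2	0.22	0.015	38	20272	5.9
T8	219	purinin		Purinin Bu-2		1	0.06	0.015	34	20592	6.2
T8	223	purinin		Purinin Bu-2		1	0.20	0.030	34	20592	6.2
T8	220	purinin		Purinin Bu-3		1	0.23	0.018	19	22371	6.2
T8	227	purinin		Purinin Bu-3		1	0.04	0.005	28	22371	6.2
T8	143	triticin	Tri-1	Triticin DR736644 N-terminal subunit		3	0.27	0.011	inc	inc	inc
T8	136	triticin	Tri-1	Triticin TC11_285558 N-terminal subunit		2	0.17	0.011	36	40501	6.2
T8	348	triticin	Tri-1	Triticin TC11_285558 N-terminal subunit		2	0.23	0.023	36	40501	6.2
T8	423	triticin	Tri-1	Triticin TC11_285558 N-terminal subunit		1	0.46	0.059	36	40501	6.2
T8	463	triticin	Tri-1	Triticin TC11_285558 N-terminal subunit		1	0.06	0.003	18	40501	6.2
T8	249	triticin	Tri-1	Triticin TC11_264477 C-terminal subunit		1	0.21	0.011	22	21830	8.1
T8	253	triticin	Tri-1	Triticin TC11_264477 C-terminal subunit		1	0.19	0.010	17	21830	8.1
T8	218	globulin		Globulin-1 ABG68030		1	0.05	0.023	48	22941	8.6
T8	104	globulin		Globulin-2 Bu-17295		1	0.02	0.004	25	53832	6.6
T8	121	globulin		Globulin-2 Bu-17295		1	0.04	0.002	23	53832	6.6
T8	99	globulin		Globulin-2 Bu-17366		1	0.03	0.002	inc	inc	7.0
T8	103	globulin		Globulin-2 Bu-18428		1	0.06	0.003	10	53554	6.6
T8	106	globulin		Globulin-2 Bu-18428		1	0.03	0.004	30	53554	6.6
T8	180	globulin		Globulin Glo-3-type TC234094		5	0.08	0.007	inc	inc	inc
T8	184	globulin		Globulin Glo-3-type TC11_305389		2	0.03	0.008	inc	inc	inc
T8	309	globulin		Globulin Glo-3-type TC11_305389		1	0.02	0.004	inc	inc	inc
T8	272	globulin		Globulin Glo-3-type TC234094/WTAI-CM3 P17314		2	0.02	0.003	nd	nd	nd
T8	174	GSP/puroindoline	Pin-D1	Grain softness protein CAA56591		1	0.02	0.001	17	16157	8.1
T8	275	GSP/puroindoline	Pin-D1	Grain softness protein CAA56586		2	0.06	0.009	30	16381	7.6
T8	248	GSP/puroindoline	Pin-D1	Puroindoline-b AAT40244		2	0.21	0.053	28	14812	9.0
T8	271	GSP/puroindoline	Pin-D1	Puroindoline-b AAT40244		1	0.04	0.015	44	14812	9.0
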