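# Gamma-gliadin spots
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T5	325	gamma-gliadin		Gamma-gliadin Bu-1 or -8		3	0.89	0.044	inc	inc	inc
T5	326	gamma-gliadin		Gamma-gliadin Bu-1		2	0.13	0.014	26	35521	7.7
T5	160	gamma-gliadin		Gamma-gliadin Bu-2		1	2.17	0.002	39	35188	8.2
T5	166	gamma-gliadin		Gamma-gliadin Bu-4		3	0.41	0.024	42	32606	8.2
T5	169	gamma-gliadin		Gamma-gliadin Bu-4		3	1.97	0.107	56	32606	8.2
T5	337	gamma-gliadin		Gamma-gliadin Bu-4		5	0.28	0.104	63	32606	8.2
T5	134	gamma-gliadin		Gamma-gliadin Bu-5		2	0.12	0.022	37	38943	7.8
T5	320	gamma-gliadin		Gamma-gliadin Bu-5		1	2.27	0.085	50	38943	7.8
T5	323	gamma-gliadin		Gamma-gliadin Bu-5		2	0.69	0.045	56	38943	7.8
T5	324	gamma-gliadin		Gamma-gliadin Bu-5		1	0.22	0.012	55	38943	7.8
T5	335	gamma-gliadin		Gamma-gliadin Bu-6		2	0.24	0.054	47	30616	8.5
T5	346	gamma-gliadin		Gamma-gliadin Bu-6		1	1.67	0.168	49	30616	8.5
T5	347	gamma-gliadin		Gamma-gliadin Bu-6		2	<0.01	0.000	32	30616	8.5
T5	339	gamma-gliadin		Gamma-gliadin Bu-7		2	0.36	0.039	52	31010	8.2
T5	163	gamma-gliadin		Gamma-gliadin Bu-11/AAD30556		1	0.38	0.037	14	32018	6.5
T5	527	gamma-gliadin		Gamma-gliadin Bu-11/AAD30556		3	0.37	0.018	32	32018	6.5
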