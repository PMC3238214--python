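# Beta-amylase, other enzyme and other protein spots
# (spot 476 is also listed with the omega-gliadins, where its volume is recorded)
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T10	476	beta-amylase		Beta-amylase Bu-1		4	-	-	32	60016	6.9
T10	537	beta-amylase		Beta-amylase Bu-1		2	0.04	0.010	18	60016	6.9
T10	94	beta-amylase		Beta-amylase Bu-2		2	0.04	0.006	47	54481	5.9
T10	462	beta-amylase		Beta-amylase Bu-2		2	0.11	0.014	60	54481	5.9
T10	64	beta-amylase		Beta-amylase Bu-3		1	0.05	0.010	13	54319	5.8
T10	92	beta-amylase		Beta-amylase Bu-3		1	0.18	0.029	34	54319	5.8
T10	93	beta-amylase		Beta-amylase Bu-3		1	0.09	0.013	55	54319	5.8
T10	89	enzyme		ADP-glucose PP lg subunit CAD98749		1	0.03	0.002	10	53030	5.6
T10	128	enzyme		ADP-glucose PP lg subunit CAD98749		1	0.10	0.047	11	53030	5.6
T10	108	enzyme		ADP-glucose PP sm subunit AAF61173		2	0.09	0.013	60	52061	5.5
T10	110	enzyme		ADP-glucose PP sm subunit AAF61173		2	0.06	0.019	24	52061	5.5
T10	118	enzyme		Alanine amino transferase TC11_282456		1	0.06	0.002	36	52820	6.1
T10	109	enzyme		ATP-synthase beta-subunit CAA52636		1	0.02	0.004	32	58562	5.4
T10	232	enzyme		Chitinase BAB18520		1	0.04	0.009	40	26095	8.7
T10	455	enzyme		Chitinase AAX83262		1	0.05	0.010	26	26022	8.3
T10	241	enzyme		Dehydroascorbate reductase TC264934		2	0.09	0.013	83	23358	5.9
T10	123	enzyme		Enolase TC11_292359		2	0.07	0.014	64	48033	5.4
T10	178	enzyme		Glyoxalase I TC11_288238		1	0.10	0.020	68	32568	5.4
T10	202	enzyme		Glucose/ribitol dehydrogenase RS_UWI_14903		1	<0.01	0.000	57	31851	6.3
T10	436	enzyme		Ketol-acid reducto isomerase TC234371		3	0.05	0.005	21	57486	5.4
T10	175	enzyme		Malate dehydrogenase AAT64932		1	0.03	0.007	41	35486	5.8
T10	176	enzyme		Malate dehydrogenase AAT64932		1	0.15	0.000	58	35486	5.8
T10	450	enzyme		Methionine synthase RS_UWI_10957		1	0.02	0.005	11	84552	5.7
T10	371	enzyme		Orthophosphate dikinase TC11_322894		1	0.03	0.004	19	73501	5.8
T10	299	enzyme		PDI3 AAK49425		3	0.14	0.016	53	54094	4.9
T10	475	enzyme		Sucrose synthase 2 CAA03935		1	0.08	0.011	19	92608	6.2
T10	189	enzyme		Thiamine biosynth enzyme TC11_308909		2	0.08	0.007	35	33167	5.7
T10	225	enzyme		Triose-phosphate isomerase CAC14917		1	0.05	0.006	38	26803	5.4
T10	239	enzyme		27K thiol reductase-like TC11_300123		1	0.16	0.037	54	23642	6.1
T10	479	enzyme		27K thiol reductase-like TC11_299048		2	0.02	0.005	16	23788	6.1
T10	311	other		Elongation factor EF1A Q03033		1	0.11	0.005	14	49169	9.2
T10	533	other		HSP70 AAB99745		1	0.08	0.009	18	71031	5.1
T10	413	other		Initiation factor Eif4A P41378		1	0.06	0.014	36	46928	5.3
T10	295	other		LTP Bu-2		1	0.04	0.009	38	9606	8.2
T10	456	other		Thaumatin-like protein TC11_283136		2	0.05	0.007	39	21408	7.9
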