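# Alpha-amylase/protease inhibitor, serpin and other inhibitor spots
table	spot_id	family	group	protein	genome	n_proteins	volume	sd	coverage	mw	pi	celiac
T9	290	amylase/protease-inhibitor		CMx1/CMx3 TC11_308146		2	0.03	0.004	57	14027	8.1
T9	281	amylase/protease-inhibitor		CMx1/CMx3 TC11_309398		3	0.23	0.029	60	13891	8.0
T9	244	amylase/protease-inhibitor		WASI P16347		1	0.17	0.027	73	19633	6.8
T9	277	amylase/protease-inhibitor		WCI CAD19440		1	0.12	0.023	60	12943	7.4
T9	283	amylase/protease-inhibitor		WDAI TC11_338524		3	0.22	0.006	68	13239	5.7
T9	286	amylase/protease-inhibitor		WDAI AAV91972		5	0.12	0.020	77	13191	5.2
T9	312	amylase/protease-inhibitor		WDAI P01085		3	0.67	0.125	74	13337	6.7
T9	289	amylase/protease-inhibitor		WMAI 223520		1	0.37	0.032	72	13342	6.2
T9	528	amylase/protease-inhibitor		WMAI 223520		1	0.13	0.022	74	13342	6.2
T9	313	amylase/protease-inhibitor		WTAI-CM1 TC11_340510		4	0.21	0.014	53	13096	6.7
T9	285	amylase/protease-inhibitor		WTAI-CM2 P16851		3	0.05	0.020	42	13034	6.2
T9	280	amylase/protease-inhibitor		WTAI-CM2 P16851		3	0.43	0.025	57	13034	6.2
T9	264	amylase/protease-inhibitor		WTAI-CM3 P17314		2	0.40	0.016	90	15832	6.7
T9	265	amylase/protease-inhibitor		WTAI-CM3 P17314		2	0.09	0.032	65	15832	6.7
T9	266	amylase/protease-inhibitor		WTAI-CM16 P16159		1	0.04	0.004	53	13437	5.0
T9	284	amylase/protease-inhibitor		WTAI-CM16 P16159		1	0.48	0.021	76	13437	5.0
T9	274	amylase/protease-inhibitor		WTAI-CM17 CAA42453		1	0.02	0.004	20	13502	4.9
T9	282	amylase/protease-inhibitor		WTAI-CM17 CAA42453		2	0.20	0.008	56	13502	4.9
T9	278	amylase/protease-inhibitor		WCI CAD19440/wheatwin-Bu-2/trypsin inhibitor TC11_315743		3	0.14	0.025	nd	nd	nd
T9	146	serpin		Serpin Bu-1 Type 1b ACN59483		1	0.07	0.004	53	37667	5.4
T9	147	serpin		Serpin Bu-1 Type 1b ACN59483		1	0.09	0.006	64	37667	5.4
T9	148	serpin		Serpin Bu-1 Type 1b ACN59483		1	0.44	0.015	57	37667	5.4
T9	158	serpin		Serpin Bu-1 or Bu-4		1	0.02	0.011	inc	inc	inc
T9	162	serpin		Serpin Bu-1 or Bu-4		1	0.02	0.005	inc	inc	inc
T9	149	serpin		Serpin Bu-2 Z1c Q9ST58		2	0.17	0.012	70	42882	5.6
T9	397	serpin		Serpin Bu-2 Z1c Q9ST58		1	0.02	0.004	18	42882	5.6
T9	398	serpin		Serpin Bu-3 Z1a P93693		1	0.04	0.006	40	43118	5.6
T9	399	serpin		Serpin Bu-3 Z1a P93693		1	0.04	0.007	24	43118	5.6
T9	159	serpin		Serpin Bu-4 or Bu-5		3	0.24	0.007	inc	inc	inc
T9	151	serpin		Serpin Bu-5 CAA72274		1	0.19	0.016	62	42981	5.2
T9	154	serpin		Serpin Bu-5 CAA72274		1	0.08	0.011	23	42981	5.2
T9	150	serpin		Serpin Bu-7 ACN59484		1	0.10	0.010	62	43431	5.1
T9	152	serpin		Serpin Bu-7 ACN59484		1	0.06	0.016	39	43431	5.1
T9	201	other-inhibitor		Tritin TC235992		4	0.15	0.017	64	29653	9.8
T9	205	other-inhibitor		Xylanase inhibitor XIP-1 1OM0		1	0.11	0.042	54	30285	8.3
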