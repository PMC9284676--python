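sample	group	lineage	Ale	Angela	Ikeros	Ivanna	SIRE	TAR	Tork	Ty1_Copia	OTA	Athila	Tat	Ogre	Retand	CRM	Tekay	Reina	Ty3_Gypsy	EnSpm_CACTA	hAT	MuDR_Mutator	PIF_Harbinger	rDNA_5S_45S	Satellite	Mobile_element	LTR	LINE	Repeat_conflict	Unclassified	Total
Festuca africana	BL	Tropical-South African	0	8.42	0	0	0.46	0.06	0	0	0	0.3	0	4.63	1.32	0.14	4.75	0	0	1.14	0	0.13	0	0.04	1.7	0	5.74	0	0	32.26	61.1
Festuca amplissima	BL	Central-South American	0	12.43	0.05	0.11	3.04	0.71	0.23	0	0	0.26	0	0.02	7.87	0.67	2.05	0	0	1.54	0	0.79	0	0.12	2.72	0	6.89	0.16	0	12.58	52.25
Festuca caldasii	BL	Central-South American	0.03	27.45	0	0.33	0.82	0.48	0.02	0	0	0.26	0	0.13	6.03	0.17	7.32	0	0	0.49	0	0.11	0	0.06	0.88	0	9.64	0	0	7.4	61.63
Festuca durandoi	BL	Subbulbosae	0	6.81	0	0	3.6	0.47	0	0	0	0.17	0	0.16	18.2	1.84	3.87	0	0	4.04	0	0.19	0.09	0.1	0.96	0	4.9	0.02	0.87	7.81	54.12
Festuca lasto	BL	Drymanthele	0	11.83	0.09	0	2.73	0.59	0.02	0	0	3.42	0	0	6.85	1.76	8.51	0	0	1.72	0	0.03	0	0.17	0.84	0	1.76	0.01	0	14.11	54.46
Festuca mekiste	BL	Tropical-South African	0	8.79	0	0.01	3.08	0.24	0	0	0	2.77	0	7.92	1.91	0.35	11.14	0	0	2.86	0	0.27	0	0.03	3.01	0	2.68	0	0	6.5	51.57
Festuca molokaiensis	BL	Subulatae-Hawaiian	0	5.94	0.03	1.26	9.96	0.03	0	0	0	0.01	0	1.55	21.35	0.26	5.71	0	0	4.95	0	1.37	0	0.25	1.12	0	1.49	0.02	1.49	7.09	63.85
Festuca paniculata	BL	Subbulbosae	0	7.51	0	0	3.75	0.43	0.02	0	0	0.45	0	0	14.83	0.81	2.3	0	0	0.51	0	0.02	0.03	0.89	0.82	2.77	5.82	0.03	0	13.16	54.14
Festuca parvigluma	BL	Subulatae-Hawaiian	0	2.99	0.12	0	1.57	0.04	0.15	0	0	0.03	0	0.01	7.16	0.65	1.93	0	0	0.82	0	0.07	0	0.38	1.34	0	2.79	0	0	26.43	46.47
Festuca scabra	BL	South African	0	6.95	0.09	0.11	0.47	0.36	0	0	0	5.69	0	4.6	6.86	1.28	14.78	0	0	2.81	0	0.54	0	0.4	2.96	0	2.57	0	0	7.61	58.08
Festuca spectabilis	BL	Leucopoa	0	8.94	0	0	2.47	0.73	0.1	0	0	0.07	0	0.12	10.48	2.38	3.54	0	0	4.13	0	0.35	0.05	0.77	2.04	0	7.32	0.2	0	7.71	51.41
Festuca superba	BL	Central-South American	0.03	21.07	0	0.9	0.68	0.49	0.01	0	0	0	0	0.01	20.31	0.05	1.54	0	0	0.92	0	0.51	0	0.26	1.4	0	11.01	0	0	5.71	64.9
Festuca triflora	BL	Lojaconoa	0	15.24	0	0	1.34	0.33	0.14	0	0	5.98	0	0.11	7.15	0.78	7.71	0	0	0.85	0	0.13	0	0.51	1.78	0	0	0	0	14.93	56.98
Festuca a. arundinacea	Sch	F.gr.arundinacea	0	2.52	0.06	0	1.36	0.29	0.01	0	0	3.07	0	0.08	7.31	1.27	1.47	0	0	1.92	0	0.03	0.07	0.63	1.53	0	7.66	0.09	0.24	9.09	38.67
Festuca a. Atlantigena	Sch	F.gr.arundinacea	0	2.84	0.02	0	0.6	0.08	0.01	0	0	0.14	0	0	11.16	1.49	7.5	0	0	1.62	0	0.06	0.03	0.37	2.13	0	6.42	0.08	0.09	11.43	46.09
Festuca dracomontana	Sch	F.gr.arundinacea	0	3.79	0.03	0	1.05	0.18	0.01	0	0	1.58	0	0.13	10.24	2.45	8.23	0	0	1.68	0	0	0	0.59	1.49	0	6.44	0.04	0.79	15.09	53.82
Festuca fenas	Sch	Mahgrebian	0	1.29	0.02	0	0.83	0.16	0	0	0	1.15	0	0	3.4	0.8	2.5	0	0	0.45	0	0	0	0.21	1.21	0	3.69	0.02	0	22.64	38.38
Festuca fontqueri	Sch	European	0	7.31	0.09	0	1.65	0.28	0.01	0	0	7.55	0	0.63	8.21	2	7.9	0	0	1.54	0	0.08	0.01	0.09	3.25	0	5.12	0.03	1.11	11.96	58.82
Festuca gigantea	Sch	European	0	5.16	0	0	0.98	0.13	0.01	0	0	0.98	0	0	6.19	3.73	2.62	0	0	1.19	0	0	0.03	0.4	8.06	0	10.76	0.1	0	17.62	57.96
Festuca gudoschnikovii	Sch	European	0	3.96	0	0	3.02	0.12	0	0	0	0.19	0	0	7.17	3.37	2.22	0	0	1.24	0	0	0.02	0.59	5.32	0	6.04	0.07	0	12.93	46.25
Festuca a. letourneuxiana	Sch	Mahgrebian	0	0.73	0.01	0	0.71	0.08	0	0.12	0.01	1.13	0	0	2.85	0.8	0.43	0	0.01	0.62	0	0	0.01	0.63	1.61	0	2.53	0.02	0	18.39	30.7
Festuca mairei	Sch	Mahgrebian	0	1.02	0.03	0.02	0.82	0.18	0	0.1	0	1.32	0	0	2.59	0.99	1.51	0	0	0.62	0	0	0	0.3	2.28	0	3.19	0	0	21.58	36.57
Festuca pratensis	Sch	European	0.04	5.41	0.01	0	3.77	0.19	0	0	0	7.18	0	0.66	14.88	4.26	4.89	0	0	2.02	0	0.01	0	0.69	1.81	0	2.17	0.01	0.4	10.29	58.72
Festuca simensis	Sch	European	0	1.9	0	0	0.62	0.01	0	0.02	0.02	0.37	0.02	0	8.04	0.91	0.4	0	0	0.66	0	0	0	0.3	12.01	0	6.95	0.01	0	28.01	60.23
Lolium canariense	Sch	Lolium	0.11	2.49	0	0	1.22	0.23	0	0	0	0.05	0	0.39	6.04	2.6	2.53	0	0	0.41	0	0.02	0	0.81	6.93	0	4.53	0	0	29.09	57.46
Lolium perenne	Sch	Lolium	0.07	4.9	0	0	0.64	0.17	0.01	0	0	25.26	0	2.79	6.12	1.75	5.47	0	0	1.09	0	0.04	0.09	1.83	2.03	0	0	0.04	1.64	8.68	62.63
Lolium persicum	Sch	Lolium	0.11	6.2	0	0	0.73	0.41	0.04	0	0	9.18	0	1.15	18.86	5.15	6.34	0	0	1.97	0	0	0.19	1.02	4.87	0	4.33	0	1.52	6.65	68.71
Lolium rigidum	Sch	Lolium	0.1	2.29	0	0	0.14	0.04	0	0	0	23.1	0	4.86	5.3	2.68	0.79	0	0	0.63	0	0	0.06	3.83	2.53	0	1.85	0	2.42	16.53	67.15
Lolium saxatile	Sch	Lolium	0.18	7.25	0.04	0	2.13	0.44	0.02	0.01	0	7.23	0	0	9.39	1.57	6.67	0.01	0	1.03	0	0	0.65	0.56	1.76	0	3.29	0.02	6.64	13.03	61.91
Micropyropsis tuberosa	Sch	European	0.05	3.38	0	0	0.33	0.01	0	0	0	0.02	0	0.05	16.89	3.58	3.93	0	0	1.5	0	0.02	1.02	1.3	3.99	0	6.07	0	1.47	20.01	63.64
Festuca abyssinica	FL	Afroalpine	0	3.65	0	0.07	0.96	0.08	0	0	0	0.15	0	1.85	3.83	0.34	1.78	0	0	1.56	0	0.41	0	0.31	4.93	0	3.45	0	0	26.92	50.27
Festuca asplundii	FL	American II	0	9.97	0.52	0	8.17	0.53	0.13	0	0	1.31	0	0.82	1.96	0.67	0.02	0	0	5.52	0	0.93	0.01	0.04	1.83	0	3.27	0	0.97	11.75	48.41
Festuca capillifolia	FL	Exaratae	0	0.75	0	0	2.32	0.14	0.01	0	0	1.58	0	0.22	4.03	1.41	4.87	0	0	1.86	0	0	0	0.65	5.16	0	9.77	0	0	24.23	57.02
Festuca chimborazensis	FL	American I	0	10.89	0.06	0.02	6.98	0.67	0	0	0.01	1.06	0	0.06	4.17	1.16	0	0	0	5.04	0	0.65	0.09	0.3	4.09	0	2.15	0	1.07	8.99	47.45
Festuca eskia	FL	Eskia	0	5.77	0.02	0.06	5.36	0.4	0	0	0	0.73	0	0.18	7.51	0.72	3.13	0	0	3.18	0	0.09	0.03	0.11	1.11	0	7.92	0.06	1.04	9.18	46.59
Festuca fimbriata	FL	American II	0.01	4.47	0.15	0.04	1.6	1.18	0.12	0.43	0	0.04	0	0.34	1.66	0.09	0.21	0	0	1.18	0	0.2	0	0.05	3.91	0	1.62	0.02	0	21.54	38.87
Festuca francoi	FL	Aulaxyper	0	0.13	0.02	0	1.17	0.16	0.01	0.02	0.09	0.85	0	0.07	1.62	0.23	0.03	0	0	0.81	0	0.02	0	0.27	4.16	0	1.07	0	0	26.83	37.56
Festuca gracillima	FL	American-Neozeylandic	0	4.5	0.15	0.02	1.74	0.61	0	0	0	0.87	0	1.22	6.05	1.54	0.01	0	0	0.76	0	0.92	0	0.61	1.45	0	8.23	0	6.04	13.95	48.68
Festuca holubii	FL	American I	0	10.87	0.07	0	6.86	0.76	0	0	0	0.61	0	0.02	3.52	1.1	0.01	0	0	4.54	0	0.54	0.01	0.42	5.96	0	0.9	0.01	0.99	13.32	50.52
Festuca ovina	FL	Festuca	0.03	0.26	0.02	0	3.16	0.33	0	0	0	7.18	0	0.59	4.26	1.04	2.04	0	0	2.01	0	0	0.01	0.28	5.22	0	2.75	0.03	7.1	12.28	48.58
Festuca pampeana	FL	American Pampas	0	0.52	0	0.06	0.63	0.1	0.06	0	0	0	0	0.33	6.47	0.03	0	0	0	0.85	0	0.19	0	1.02	4.77	0	2.85	0	0	23.59	41.48
Festuca pirenaica	FL	Exaratae	0	10.88	0.36	0	7.1	0.6	0.12	0	0.01	0.87	0	0.34	4.32	1.48	0.21	0	0	4.67	0	0.8	0	0.05	2.66	0	0	0	2.09	11.66	48.21
Festuca procera	FL	American II	0.01	4.47	0.11	0	3.53	0.36	0.03	0	0	1.31	0	0.26	3.46	1.41	0.42	0	0	2.62	0	0.01	0	0.37	5.94	0	7.32	0.04	0.96	10.43	43.08
Festuca pyrogea	FL	Festuca	0.04	0.02	0	0	0.08	0	0	0.03	0	0	0	0	6.91	0.02	0.49	0	0	0.95	0	0	0	0.42	13.4	0	1.24	0	0	24.13	47.73
Festuca rubra	FL	Aulaxyper	0	0.08	0	0	0.96	0.3	0.01	0	0	8.55	0	0.61	2.11	0.69	1.24	0	0	0.95	0	0.01	0	0.7	6.56	0	0.76	0	0.32	22.79	46.65
Megalachne masafuerana	FL	American Pampas	0	1.44	0	0.18	0.38	1.98	0	0.02	0	0.1	0	0	7.4	3.31	0	0	0	1.4	0.03	0	0	0.4	1.88	0	2.74	0.04	0.14	23.85	45.28
Vulpia ciliata	FL	Psilurus-Vulpia	0.14	3.81	0	0	0.78	0.49	0.16	0	0.01	0.22	0	0.08	16.79	0.86	0.56	0	0	1.6	0	0.11	0	0.7	2.76	0	8.45	0.33	2.33	11.74	51.91
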