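sample	group	ploidy	c2_pg	cx1_pg	cx1_mbp
Festuca caldasii	BL	4	20.36	5.09	4978.02
Festuca durandoi	BL	4	14.66	3.66	3584.86
Festuca paniculata	BL	2	7.65	3.83	3740.85
Festuca triflora	BL	2	7.84	3.92	3833.76
Festuca asplundii	FL	6	21.23	3.54	3460.49
Festuca chimborazensis	FL	6	13.48	2.25	2197.24
Festuca eskia	FL	2	5.7	2.85	2787.3
Festuca ovina	FL	2	4.82	2.41	2356.98
Festuca procera	FL	4	14.88	3.72	3638.16
Festuca rubra	FL	6	13.68	2.28	2229.84
Vulpia ciliata	FL	4	8.28	2.07	2024.46
Festuca a. arundinacea	Sch	6	17.46	2.91	2845.98
Festuca a. atlantigena	Sch	8	16.22	2.03	1982.895
Festuca a. letourneuxiana	Sch	10	19.7	1.97	1926.66
Festuca fenas	Sch	4	10.48	2.62	2562.36
Festuca fontqueri	Sch	2	5.54	2.77	2709.06
Festuca gigantea	Sch	6	20.75	3.46	3382.25
Festuca mairei	Sch	4	10.04	2.51	2454.78
Festuca pratensis	Sch	2	6.5	3.25	3178.5
Lolium canariense	Sch	2	4.3	2.15	2102.7
Lolium perenne	Sch	2	5.51	2.76	2694.39
Lolium persicum	Sch	2	6.4	3.2	3129.6
Lolium rigidum	Sch	2	5.49	2.75	2684.61
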