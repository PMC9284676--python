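sample	ploidy	n_reads	genome_proportion_pct	repeat_size_bp	kmer_score	connected_component_index	shape_type
Festuca abyssinica	4x	180	0.036	316	0.885	0.967	1
Festuca africana	10x	214	0.043	317	0.488	0.879	2
Festuca amplissima	6x	158	0.032	318	0.744	0.994	1
Festuca a. arundinacea	6x	369	0.074	315	0.78	0.987	1
Festuca a. letourneuxiana	10x	532	0.11	307	0.721	0.974	2
Festuca a. atlantigena	8x	428	0.086	307	0.791	0.981	2
Festuca asplundii	6x	110	0.022	318	0.894	0.982	1
Festuca capillifolia	2x	340	0.068	318	0.9	0.976	1
Festuca chimborazensis	6x	179	0.036	319	0.845	0.899	2
Festuca dracomontana	–	629	0.13	307	0.75	0.936	1
Festuca durandoi	2x	520	0.1	318	0.812	0.994	2
Festuca eskia	2x	525	0.1	319	0.873	0.989	2
Festuca fenas	4x	222	0.044	307	0.781	0.973	1
Festuca fimbriata	6x	104	0.021	317	0.8	0.923	1
Festuca fontqueri	2x	470	0.094	296	0.824	0.977	2
Festuca francoi	2x	632	0.13	317	0.748	0.981	2
Festuca holubii	–	179	0.036	318	0.863	0.944	2
Festuca lasto	2x	470	0.094	296	0.824	0.977	1
Festuca mairei	4x	330	0.066	315	0.791	0.921	1
Festuca mekiste	–	109	0.022	317	0.619	0.917	1
Festuca molokaiensis	–	208	0.042	316	0.666	0.861	2
Festuca ovina	2x	331	0.066	316	0.952	0.985	1
Festuca pampeana	8x	402	0.08	317	0.812	0.98	1
Festuca paniculata	2x	269	0.054	318	0.781	0.978	2
Festuca parvigluma	4x	190	0.038	316	0.711	0.884	1
Festuca pratensis	2x	447	0.089	545	0.832	0.911	2
Festuca procera	4x	165	0.033	317	0.863	0.976	2
Festuca pyrenaica	4x	204	0.041	316	0.62	0.941	2
Festuca pyrogea	–	850	0.17	326	0.602	0.955	2
Festuca rubra	6x	338	0.068	316	0.737	0.87	2
Festuca scabra	4x	232	0.046	301	0.782	0.978	2
Festuca simensis	4x	412	0.082	296	0.675	0.951	2
Festuca spectabilis	6x	1128	0.23	316	0.791	0.99	2
Festuca superba	8x	184	0.037	316	0.772	0.995	1
Festuca triflora	2x	217	0.043	262	0.498	0.982	2
Lolium canariense	2x	306	0.061	294	0.842	0.974	1
Lolium perenne	2x	447	0.089	307	0.868	0.982	1
Lolium persicum	2x	1154	0.23	307	0.832	0.976	1
Lolium rigidum	2x	892	0.18	307	0.809	0.983	1
Lolium saxatile	2x	157	0.031	308	0.914	0.975	2
Megalachne masafuerana	–	690	0.14	224	0.438	0.997	2
Micropyropsis tuberosa	2x	911	0.18	307	0.865	0.98	1
Vulpia ciliata	4x	414	0.083	315	0.916	0.993	2
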