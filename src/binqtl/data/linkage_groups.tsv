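chromosome	n_bins	length_cm	avg_distance_cm	avg_bin_length_kb	rate_cm_per_mb	n_rhr
A01	234	168.32	0.72	505.01	1.42	104
A02	197	159.41	0.81	549.60	1.47	76
A03	254	180.2	0.71	439.31	1.61	113
A04	239	234.94	0.98	366.91	2.68	110
A05	256	272.68	1.07	433.02	2.46	147
A06	206	167.24	0.81	614.00	1.32	99
A07	255	191.84	0.75	378.80	1.99	138
A08	189	126.69	0.67	661.70	1.01	78
A09	262	189.01	0.72	317.60	2.27	150
A10	326	208.36	0.64	353.10	1.81	151
A11	405	284.58	0.7	299.70	2.34	219
A12	284	210.33	0.74	378.80	1.95	166
A13	348	269.64	0.77	317.12	2.44	166
D01	232	154.67	0.67	278.90	2.39	119
D02	257	199.83	0.78	271.50	2.86	115
D03	173	152.18	0.88	311.50	2.82	91
D04	157	134.93	0.86	362.60	2.37	95
D05	282	233.47	0.83	226.70	3.65	207
D06	221	180.13	0.82	296.21	2.75	103
D07	173	189.57	1.10	337.71	3.25	107
D08	217	187.01	0.86	318.31	2.71	127
D09	185	185.67	1.00	281.12	3.57	121
D10	228	199.29	0.87	293.32	2.98	126
D11	317	218.19	0.69	225.10	3.06	200
D12	195	195.58	1.00	316.40	3.17	143
D13	211	163.37	0.77	305.40	2.53	109
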