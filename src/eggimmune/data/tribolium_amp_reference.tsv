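gene_id	name	mw_kda	length_aa	hydrophobic_pct	net_charge	glycine_pct	proline_pct	fold_wildtype	fold_control	known
TC000499	Cecropin1	3.67	31	58	5	6	0	Inf	Inf	yes
TC000500	Cecropin3	9.80	90	43	2	6	13	Inf	49	yes
TC007738	attacin2	15.80	145	37	7	12	4	3098	2190	yes
TC005093	Coleoptericin1	15.99	141	30	-1	9	7	2392	18067	yes
TC010517	Defensin2	8.73	79	50	6	6	1	1183	Inf	yes
TC012469	Defensin3	9.42	83	50	7	3	1	908	Inf	yes
TC007737	attacin1	17.49	165	28	9	18	3	869	3696	yes
TC007858		20.14	182	35	0	11	3	484	54	no
TC006250	Defensin1	14.91	132	46	1	14	3	187	1551	yes
TC011036		12.89	109	39	1	32	6	138	11	no
TC005096	Coleoptericin2	15.96	141	30	-1	9	7	91	227	yes
TC015479		13.00	120	42	6	5	1	80	26	no
TC007763		16.87	158	37	4	6	17	47	67	no
TC004646		15.04	135	34	2	7	7	40	29	no
TC008806		15.83	142	33	2	10	2	31	37	no
TC009336		13.50	137	30	-4	39	2	15	7	no
TC014565		20.73	176	38	17	2	2	14	9	no
TC001030		14.62	137	29	9	10	12	9	16	no
TC001784		13.54	150	27	7	43	2	8	6	no
TC005478		13.70	122	45	10	4	1	6	7	no
TC015612		20.32	182	36	7	6	6	6	2	no
TC007901		7.25	64	25	5	7	10	6	5	no
TC015304		19.30	180	38	2	6	9	5	no hit	no
TC011733		11.89	106	46	3	2	0	5	5	no
TC003374		12.22	124	61	3	1	9	2	9	no
TC008557		17.82	172	31	2	18	0	3	5	no
TC015754		15.69	140	34	5	4	7	2	2	no
TC000435		11.84	105	37	5	5	0	2	2	no
TC009096		12.84	111	16	16	9	6	2	2	no
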