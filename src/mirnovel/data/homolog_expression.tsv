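name	CTL13	CTL14	CTL15	CTL16	AA19	AA20	AA21	AA22	aCTL13	aCTL14	aCTL15	aAA19	aAA20	aAA21
rno-miR-1839-5p	8162	7238	8496	5294	6110	6872	5256	5137	85.42	92.51	82.01	63.97	129.1	37.79
rno-miR-1839-3p	378	389	389	462	409	474	402	482	9.28	18.79	8.19	6.79	27.95	2.46
rno-miR-3068-5p	2288	2212	2190	3636	2506	1935	1884	5459	14.85	12.03	16.36	44.82	7.27	27.57
rno-miR-3068-3p	1477	1593	1775	1208	1285	1270	1169	1128	5.35	16.6	22.47	25.82	7.16	30.01
rno-miR-1843-5p	1181	970	1063	634	745	806	848	715	11.81	6.07	6.87	11.23	9.49	11.4
rno-miR-1843-3p	165	181	172	148	101	239	206	167	4.13	11.73	14.4	13.19	6.97	9.04
rno-miR-509-5p	9	16	30	10	8	8	36	12	0.67	0.03	1.11	0.02	0	3.19
rno-miR-509-3p	53	34	46	23	11	15	52	47	0	2.58	0.01	0.03	0	1.92
rno-miR-1306-5p	11	13	4	10	12	21	17	28	0	6.71	0.02	20.73	0	1.94
rno-miR-1306-3p	0	0	1	1	0	0	0	4	94.92	89.46	53.45	24.31	42.25	130.4
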