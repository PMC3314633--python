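name	CTL13	CTL14	CTL15	CTL16	AA19	AA20	AA21	AA22	aCTL13	aCTL14	aCTL15	aAA19	aAA20	aAA21
rno-miR-3598	80	88	81	80	150	109	80	289	164	173	180	312	315	391
rno-miR-3599	90	70	129	67	43	89	84	51	134	173	74	73	52	166
rno-miR-3600	3058	2741	1838	343	1095	1152	1595	592	316	236	223	164	133	254
rno-miR-3601	17	15	34	11	25	28	28	15	42968	33213	39003	47376	25834	48927
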