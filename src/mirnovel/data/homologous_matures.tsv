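name	precursor	arm	is_mature	sequence	chrom	start	end	strand
rno-miR-1839-5p	rno-mir-1839	5p	1	AAGGUAGAUAGAACAGGUCUUG	1	137744048	137744110	+
rno-miR-1839-3p	rno-mir-1839	3p	0	AGACCUACUUAUCUACCAACAG	1	137744048	137744110	+
rno-miR-3068-5p	rno-mir-3068	5p	1	UUGGAGUUCAUGCAAGUUCUAACCA	6	111674240	111674314	-
rno-miR-3068-3p	rno-mir-3068	3p	0	GGUGAAUUGCAGUACUCCAACA	6	111674240	111674314	-
rno-miR-1843-5p	rno-mir-1843	5p	1	UAUGGAGGUCUCUGUCUGACU	6	103413903	103413991	-
rno-miR-1843-3p	rno-mir-1843	3p	0	UCUGAUCGUUCACCUCCAUACA	6	103413903	103413991	-
rno-miR-509-5p	rno-mir-509	5p	1	UACUCCAGAAUAUGGCAAUCAUG	X	154190989	154191072	-
rno-miR-509-3p	rno-mir-509	3p	0	UGAUUGACAUGUCUGCAGUGGA	X	154190989	154191072	-
rno-miR-1306-5p	rno-mir-1306	5p	1	CCACCUCCCCUGCAAACGUCCA	11	84703718	84703789	+
rno-miR-1306-3p	rno-mir-1306	3p	0	GACGUUGGCUCUGGUGGUGAUG	11	84703718	84703789	+
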