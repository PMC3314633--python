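name	homolog_ids	homolog_sequence
rno-miR-1839-5p	cfa-miR-1839;mmu-miR-1839-5p;bta-miR-1839;eca-miR-1839;ssc-miR-1839-5p	AAGGUAGAUAGAACAGGUCUUG
rno-miR-1839-3p	mmu-miR-1839-3p	AGACCUACUUAUCUACCAACAG
rno-miR-3068-5p	mmu-miR-3068	UUGGAGUUCAUGCAAGUUCUAACC
rno-miR-3068-3p	mmu-miR-3068*	GGUGAAUUGCAGUACUCCAACA
rno-miR-1843-5p	mmu-miR-1843-5p	UAUGGAGGUCUCUGUCUGACU
rno-miR-1843-3p	mmu-miR-1843-3p	UCUGAUCGUUCACCUCCAUACA
rno-miR-509-5p	mmu-miR-509-5p	UACUCCAGAAUGUGGCAAUCAU
rno-miR-509-3p	age-miR-509b;age-miR-509a	UGAUUGACACGUCUGCAGAUAGA
rno-miR-1306-5p	ssc-miR-1306-5p	CCACCUCCCCUGCAAACGUCCA
rno-miR-1306-3p	mmu-miR-1306-3p;ssc-miR-1306-3p	ACGUUGGCUCUGGUGGUGAU
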