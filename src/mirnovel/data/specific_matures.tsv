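name	precursor	sequence	chrom	start	end	strand
rno-miR-3598	rno-mir-3598	UCUAGGGCUGGAGAGAUGGCUA	13	40705693	40705785	+
rno-miR-3599	rno-mir-3599	AUUAGGGUUGCAGAGCCAGG	5	158395573	158395709	-
rno-miR-3600	rno-mir-3600	UGUGGACUUGGAGUCAGAAGG	5	5156340	5156444	-
rno-miR-3601	rno-mir-3601	GAUACACAGAGGCAGGAGGAGAA	3	41992498	41992610	-
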