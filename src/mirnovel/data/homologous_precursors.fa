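>rno-mir-1839
GAAAAGGUAGAUAGAACAGGUCUUGUUUGCAAAAUAAAUUCAAGACCUACUUAUCUACCAACAG
>rno-mir-3068
AAGAGUAAUUGGAGUUCAUGCAAGUUCUAACCAGUUUAACCAGUAGCUGGGUGAAUUGCAGUACUCCAACAUUCUG
>rno-mir-1843
AGCGGUCCUACAUGAAUAUGGAGGUCUCUGUCUGACUUAGAAUAGUUGGCUAAGUCUGAUCGUUCACCUCCAUACAACUUUUAGACUGUC
>rno-mir-509
CUGUGUGUGGUUCUUUACUCCAGAAUAUGGCAAUCAUGCAUAAUUAAAUGUGAUUGACAUGUCUGCAGUGGAGUAACACAUGCAA
>rno-mir-1306
AGUCUCCACCACCUCCCCUGCAAACGUCCAGUGAUGCAGAGGUAAUGGACGUUGGCUCUGGUGGUGAUGGACA
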