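>rno-mir-3598
AUCACAGUCCUAUUUCUGCCCUCAAAGACAAAAAUGAUGUCUAGGGCUGGAGAGAUGGCUAAGUGGG
>rno-mir-3599
ACCCCUGCCCCUGUGCUCUAGCACACUGCUCAGAAAACGUUUAGGGUUGCAGAGCCAGGGUGGGGGG
>rno-mir-3600
AGGAGAACAGUGGACUUGGAGUCAGAAGGUCUGUGUGGAACUGGGCCUCCGACAUGGACUAUCACUGACCAUGAUUCCAUUCCG
>rno-mir-3601
GAGGUGUUUGCUGGAUACACAGAGGCAGGAGGAGAAAGAAGUAUUUCCUCCUGCAUCUGUGUGUAUAGCAGGCACUUU
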