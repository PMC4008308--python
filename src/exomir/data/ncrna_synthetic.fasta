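>ncrna_01 class=rRNA synthetic=true
TCCGGAAACAAATAGTTGTGACTACTGTATTCTGGTACATTTGGCCGCTCTACAGATTAATAAATCGGAA
TCCATCGCTCGAGCTTATCCGCTTTAGCGT
>ncrna_02 class=rRNA synthetic=true
ATCCTGGGTCCTTTGTGGAAAGTGCCTGGCATCGGCTCTTGCTAATGCGCTAAAAAACAAATGGTCCATC
AATTTGCCGACCTGAGTGTCTAACCAGCAGACTAAACTTA
>ncrna_03 class=rRNA synthetic=true
TGGCTGCGACAGGTTGTATTTTAGCTCACTGACCGCCAGAGGTCATGTAAATTAACTTAGCACGGCGTCA
TGCCACGCGATTTGGT
>ncrna_04 class=tRNA synthetic=true
CGGCCTCGTTAGGGTGGTTCACTGCTCGAAGCGGCCAAGTCGCTAGTGCCTTTCTTACAACCAGAACAGG
TGATATCGGACATGTTTGCGCGAGATTAACAGGGTCATCTGAATCTTA
>ncrna_05 class=tRNA synthetic=true
CGTATGTACGCGATTCGCGATAGAAGCGGGAAGGCGATCGCCGCATCCATTAATGCTGAGTTCGG
>ncrna_06 class=snRNA synthetic=true
ACGGCTGAACTGCTCTCCCTGGTTAGTCAGGCAAAACTTACACGGTTCCGAAACATTAAAACGTGTAACC
GACCTCGACACCCGGTATTTAAG
>ncrna_07 class=snoRNA synthetic=true
GGGGACCTGTTTTGAGGTCCCCTTGGATTCATAAGAGGGTCGGTTTTGCATCCTGGTTGGCTCAAGTTCT
GATCTTGACCTTCGTTAACTTT
>ncrna_08 class=scRNA synthetic=true
TAAGCACTCTAAGGGGATACGCATATTATAGCCTGAGGTTTACCATGATCATTAGGGTGTTGCCCAGTGT
CATCCAACCATACCATTATTGGGCGGCATCGGGGATTCACC
>ncrna_09 class=srpRNA synthetic=true
GCACACTCCGAGTCCTTTAGTCTAGGTATTATGCGTAGCGCTATACATTAGGGAATAAGCGGTCCGTCGC
GAGTCGAGCCGTCTAGCCTACT
>ncrna_10 class=repeat synthetic=true
GGCATGACGATGTGTGGCGAAGGTTTGCCTAATTTACTGGAGCGCTATGATTGGACATGTGGCGGGACAG
CCTGTCATAACCGCAACTTC
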