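>ssc-let-7e species=ssc
TGAGGTAGGAGGTTGTATAGTT
>ssc-let-7c species=ssc
TGAGGTAGTAGGTTGTATGGT
>ssc-miR-21 species=ssc
TAGCTTATCAGACTGATGTTGA
>ssc-miR-206 species=ssc
TGGAATGTAAGGAAGTGTGTG
>ssc-miR-140 species=ssc
CAGTGGTTTTACCCTATGGTA
>ssc-miR-92b-5p species=ssc
TTATAGGGACGGGACGCGGTG
>ssc-miR-22-3p species=ssc
AAGCTGCCAGTTGAAGAACTG
>ssc-miR-28-5p species=ssc
GAAGGAGCTCACACTCTATTGA
>ssc-miR-205 species=ssc
TCCTTCATTCCACCGGAGTCT
>ssc-miR-451 species=ssc
AAACCGTTACCATTACTGAGTT
>ssc-miR-125b species=ssc
TCCCTGAGACCCTAACTTGTG
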