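>mmu-miR-290-5p
ACTCAAACTGGGGGCTCTTT
>hsa-miR-378c
ACTGGACTTGGAGTCAGAAGGC
>hsa-miR-20b-3p
ACTGTAGTATGGGCACTTCCAG
>bta-miR-219-3p
AGAATTGTGGCTGGACATCTGT
>mmu-miR-138-5p
AGCTGGTGTTGTGAATCAGGCCG
>hsa-miR-31-5p
AGGCAAGATGCTGGCATAGCT
>rno-let-7f-1-3p
CTATACAATCTATTGCCTTCC
>mmu-miR-874-3p
CTGCCCTGGCCCGAGGGACCGA
>hsa-miR-551a
GCGACCCACTCTTGGTTTCCA
>mmu-miR-150-5p
TCTCCCAACCCTTGTACCAGTG
>hsa-let-7f-5p
TGAGGTAGTAGATTGTATAGTT
>dre-miR-182
TTTGGCAATGGTAGAACTCACA
>hsa-miR-96-5p
TTTGGCACTAGCACATTTTTGCT
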