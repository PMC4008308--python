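>IGF1R_3UTR_WT reporter insert, wild type (104 bp)
TCCTGGATCCCGATCCCGTGCAAACAGTACCGTGCGCACGCGGGCGGGCGGGGGGAGAGTTTTAACAATC
TATTCACAAGCCTCCTGTACCTCAGTGGATCTTC
>IGF1R_3UTR_DEL reporter insert, 12-nt site deletion (92 bp)
TCCTGGATCCCGATCCCGTGCAAACAGTACCGTGCGCACGCGGGCGGGCGGGGGGAGAGTTTTAACAATC
TATTCACAAGCCTCCTGTACCC
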