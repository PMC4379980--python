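>tRNA-iMet
GGGGGTAACTCAGTGCCA
>tRNA-Lys
GATGCGGGGTTAGGACCA
>tRNA-Arg
GCCGGTCTAAGGAGGCCA
>tRNA-Gly
CGTGGTCTTCGGTACCCA
>tRNA-Trp
TGGGTCCAATTTAAACCA
>tRNA-Asp
GATAATACTCGACACCCA
>tRNA-Ser
TATGAGAGTGTGTCGCCA
>tRNA-Leu
TAGTACATGGAGGGGCCA
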