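>AsLOV2_408-543 synthetic reverse-translated CDS (reconstruction)
CTGGAACGTATTGAAAAAAATTTTGTTATTACTGATCCTCGTCTGCCTGATAATCCTATT
ATTTTTGCTTCTGATTCTTTTCTGCAGCTGACTGAATATTCTCGTGAAGAAATTCTGGGT
CGTAATTGTCGTTTTCTGCAGGGTCCTGAAACTGATCGTGCTACTGTTCGTAAAATTCGT
GATGCTATTGATAATCAGACTGAAGTTACTGTTCAGCTGATTAATTATACTAAATCTGGT
AAAAAATTTTGGAATCTGTTTCATCTGCAGCCTATGCGTGATCAGAAAGGTGATGTTCAG
TATTTTATTGGTGTTCAGCTGGATGGTACTGAACATGTTCGTGATGCTGCTGAACGTGAA
GGTGTTATGCTGATTAAAAAAACTGCTGAAAATATTGATGAAGCTGCT
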