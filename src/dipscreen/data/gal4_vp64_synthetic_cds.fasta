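>Gal4_1-147_VP64 synthetic reverse-translated CDS (reconstruction, incl. TAA stop)
ATGAAACTGCTGTCTTCTATTGAACAGGCTTGTGATATTTGTCGTCTGAAAAAACTGAAA
TGTTCTAAAGAAAAACCTAAATGTGCTAAATGTCTGAAAAATAATTGGGAATGTCGTTAT
TCTCCTAAAACTAAACGTTCTCCTCTGACTCGTGCTCATCTGACTGAAGTTGAATCTCGT
CTGGAACGTCTGGAACAGCTGTTTCTGCTGATTTTTCCTCGTGAAGATCTGGATATGATT
CTGAAAATGGATTCTCTGCAGGATATTAAAGCTCTGCTGACTGGTCTGTTTGTTCAGGAT
AATGTTAATAAAGATGCTGTTACTGATCGTCTGGCTTCTGTTGAAACTGATATGCCTCTG
ACTCTGCGTCAGCATCGTATTTCTGCTACTTCTTCTTCTGAAGAATCTTCTAATAAAGGT
CAGCGTCAGCTGACTGTTTCTGGTTCTGATGCTCTGGATGATTTTGATCTGGATATGCTG
GGTTCTGATGCTCTGGATGATTTTGATCTGGATATGCTGGGTTCTGATGCTCTGGATGAT
TTTGATCTGGATATGCTGGGTTCTGATGCTCTGGATGATTTTGATCTGGATATGCTGTAA
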