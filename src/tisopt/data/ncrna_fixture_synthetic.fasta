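>syn_ncRNA_1 synthetic fixture, not a biological ncRNA
TGCGTCATAAAAGAACACATACGGTTGCTTCTATCGGCTTCAAGCTATGTGCCGATAATC
CA
>syn_ncRNA_2 synthetic fixture, not a biological ncRNA
CGTAAATACTGGTAATACGCCGGTTCTCAAAGCCTACCATACGATGGTGGTCAACCG
>syn_ncRNA_3 synthetic fixture, not a biological ncRNA
CATTATTCTCTGGAATATGCGGCTATAACTAAGTCATTCGGGGGTCGGTAAGCTGGGCCG
CATTGCATGACCCGAC
>syn_ncRNA_4 synthetic fixture, not a biological ncRNA
GTTAGCGCCCTTTGCTTAGCGAGTTGCAATCTCTGCCAGGTAGTATCAATGCAGCACT
>syn_ncRNA_5 synthetic fixture, not a biological ncRNA
GGTAGCATGCCGTTCCTACAGTTAGTCTGGTTACATCCATACACCAATTATG
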