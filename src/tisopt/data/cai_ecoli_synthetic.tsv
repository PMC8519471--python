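# cai_ecoli_synthetic: synthetic stand-in table (relative adaptiveness from a synthetic reference set); not the published Sharp & Li weights
codon	weight
AAA	0.949392
AAC	1.000000
AAG	1.000000
AAT	0.046344
ACA	0.201300
ACC	0.276718
ACG	1.000000
ACT	0.180144
AGA	0.525215
AGC	0.957512
AGG	0.051096
AGT	0.507787
ATA	0.494957
ATC	0.834526
ATG	1.000000
ATT	1.000000
CAA	1.000000
CAC	0.726186
CAG	0.211532
CAT	1.000000
CCA	0.365834
CCC	0.550625
CCG	1.000000
CCT	0.609112
CGA	1.000000
CGC	0.090878
CGG	0.058234
CGT	0.062268
CTA	0.230265
CTC	0.642987
CTG	0.460564
CTT	1.000000
GAA	0.029405
GAC	1.000000
GAG	1.000000
GAT	0.293666
GCA	0.182776
GCC	0.618249
GCG	0.996722
GCT	1.000000
GGA	0.208494
GGC	0.556409
GGG	1.000000
GGT	0.579765
GTA	0.531171
GTC	0.340803
GTG	0.952836
GTT	1.000000
TAC	1.000000
TAT	0.653966
TCA	0.253648
TCC	0.437435
TCG	0.397587
TCT	1.000000
TGC	1.000000
TGG	1.000000
TGT	0.318364
TTA	0.916096
TTC	0.151835
TTG	0.205112
TTT	1.000000
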