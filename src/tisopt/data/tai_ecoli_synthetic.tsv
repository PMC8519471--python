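# tai_ecoli_synthetic: synthetic stand-in table; not the published Tuller et al. tAI weights
codon	weight
AAA	0.510865
AAC	0.790470
AAG	1.000000
AAT	1.000000
ACA	0.122274
ACC	0.954701
ACG	1.000000
ACT	0.448008
AGA	1.000000
AGC	0.624986
AGG	0.127382
AGT	0.117595
ATA	1.000000
ATC	0.656630
ATG	1.000000
ATT	0.710115
CAA	1.000000
CAC	1.000000
CAG	0.242702
CAT	0.161169
CCA	1.000000
CCC	0.601933
CCG	0.493248
CCT	0.725031
CGA	0.595028
CGC	0.864083
CGG	0.170036
CGT	0.703067
CTA	0.120225
CTC	1.000000
CTG	0.038123
CTT	0.161192
GAA	0.175243
GAC	1.000000
GAG	1.000000
GAT	0.495877
GCA	0.212257
GCC	1.000000
GCG	0.094149
GCT	0.775297
GGA	0.010000
GGC	0.010000
GGG	1.000000
GGT	0.082871
GTA	0.196061
GTC	0.220789
GTG	0.161943
GTT	1.000000
TAC	0.170436
TAT	1.000000
TCA	0.373587
TCC	1.000000
TCG	0.183345
TCT	0.330485
TGC	0.670269
TGG	1.000000
TGT	1.000000
TTA	0.034904
TTC	1.000000
TTG	0.037575
TTT	0.512376
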