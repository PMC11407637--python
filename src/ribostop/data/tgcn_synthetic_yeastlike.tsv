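anticodon	copy_number
AAA	5
AAC	9
ACC	7
AGA	13
AGG	11
ATA	6
ATG	15
ATT	6
CAG	13
CCA	12
CCG	16
CCT	12
CGC	2
CGT	1
GAT	1
GCA	4
GCG	10
GCT	7
GGA	1
GGT	8
GTC	2
GTG	5
GTT	12
TAA	16
TAC	11
TAG	3
TAT	8
TCC	4
TGC	15
TGG	9
TTC	1
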