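# Synthetic Drosophila melanogaster codon-usage table (per-1000 counts).
# Constructed to reproduce the well-described qualitative codon preferences of the
# D. melanogaster genome (C/G-ending optimal codons for most amino acids).  It is a
# stand-in for a genome-wide usage table: supply your own table (e.g. a Kazusa-style
# export) to reproduce the usage of a specific annotation release.
codon	count
TTT	12.6
TTC	21.8
TTA	3.7
TTG	13.5
CTT	8.3
CTC	14.0
CTA	6.9
CTG	42.3
ATT	16.2
ATC	22.5
ATA	9.0
ATG	23.6
GTT	9.8
GTC	13.8
GTA	5.5
GTG	27.3
TCT	7.5
TCC	21.0
TCA	9.3
TCG	18.9
AGT	11.0
AGC	24.7
CCT	6.8
CCC	17.2
CCA	10.2
CCG	15.8
ACT	8.3
ACC	21.8
ACA	10.1
ACG	12.6
GCT	13.9
GCC	33.5
GCA	10.7
GCG	9.9
TAT	9.4
TAC	17.6
CAT	9.9
CAC	15.7
CAA	15.4
CAG	35.0
AAT	20.1
AAC	25.8
AAA	16.5
AAG	39.0
GAT	26.2
GAC	22.6
GAA	19.6
GAG	40.1
TGT	5.9
TGC	8.9
TGG	10.0
CGT	8.8
CGC	17.0
CGA	8.6
CGG	7.4
AGA	4.7
AGG	6.3
GGT	11.0
GGC	25.0
GGA	17.5
GGG	3.9
TAA	0.7
TAG	0.5
TGA	0.4
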