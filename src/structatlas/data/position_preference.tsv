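#name	position_preference
#k	3
#units	fractional preference
#citation	Satchwell SC, Drew HR, Travers AA (1986) J Mol Biol 191:659-675 (nucleosome core trinucleotide preferences)
#strand_symmetric	true
AAA	-0.36
AAC	-0.06
AAG	0.06
AAT	-0.3
ACA	0.06
ACC	0.08
ACG	0.11
ACT	0.11
AGA	-0.09
AGC	0.25
AGG	0.08
AGT	0.11
ATA	-0.13
ATC	0.07
ATG	0.18
ATT	-0.3
CAA	-0.09
CAC	0.17
CAG	-0.02
CAT	0.18
CCA	0.08
CCC	0.13
CCG	0.02
CCT	0.08
CGA	0.31
CGC	0.25
CGG	0.02
CGT	0.11
CTA	-0.18
CTC	0.08
CTG	-0.02
CTT	0.06
GAA	-0.12
GAC	0.08
GAG	0.08
GAT	0.07
GCA	0.13
GCC	0.45
GCG	0.25
GCT	0.25
GGA	-0.05
GGC	0.45
GGG	0.13
GGT	0.08
GTA	-0.06
GTC	0.08
GTG	0.17
GTT	-0.06
TAA	-0.2
TAC	-0.06
TAG	-0.18
TAT	-0.13
TCA	0.08
TCC	-0.05
TCG	0.31
TCT	-0.09
TGA	0.08
TGC	0.13
TGG	0.08
TGT	0.06
TTA	-0.2
TTC	-0.12
TTG	-0.09
TTT	-0.36
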