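codon	aa	fraction
TTT	F	0.46
TTC	F	0.54
TTA	L	0.08
TTG	L	0.13
CTT	L	0.13
CTC	L	0.20
CTA	L	0.07
CTG	L	0.40
ATT	I	0.36
ATC	I	0.47
ATA	I	0.17
ATG	M	1.00
GTT	V	0.18
GTC	V	0.24
GTA	V	0.12
GTG	V	0.46
TCT	S	0.19
TCC	S	0.22
TCA	S	0.15
TCG	S	0.05
AGT	S	0.15
AGC	S	0.24
CCT	P	0.29
CCC	P	0.32
CCA	P	0.28
CCG	P	0.11
ACT	T	0.25
ACC	T	0.36
ACA	T	0.28
ACG	T	0.11
GCT	A	0.27
GCC	A	0.40
GCA	A	0.23
GCG	A	0.11
TAT	Y	0.44
TAC	Y	0.56
TAA	*	0.30
TAG	*	0.24
TGA	*	0.47
CAT	H	0.42
CAC	H	0.58
CAA	Q	0.27
CAG	Q	0.73
AAT	N	0.47
AAC	N	0.53
AAA	K	0.43
AAG	K	0.57
GAT	D	0.46
GAC	D	0.54
GAA	E	0.42
GAG	E	0.58
TGT	C	0.46
TGC	C	0.54
TGG	W	1.00
CGT	R	0.08
CGC	R	0.18
CGA	R	0.11
CGG	R	0.20
AGA	R	0.21
AGG	R	0.21
GGT	G	0.16
GGC	G	0.34
GGA	G	0.25
GGG	G	0.25
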