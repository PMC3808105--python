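codon	amino_acid	degeneracy	hydropathy	aromatic
TTT	F	2	2.8	1
TTC	F	2	2.8	1
TTA	L	6	3.8	0
TTG	L	6	3.8	0
TCT	S	6	-0.8	0
TCC	S	6	-0.8	0
TCA	S	6	-0.8	0
TCG	S	6	-0.8	0
TAT	Y	2	-1.3	1
TAC	Y	2	-1.3	1
TAA	*	0		
TAG	*	0		
TGT	C	2	2.5	0
TGC	C	2	2.5	0
TGA	*	0		
TGG	W	1	-0.9	1
CTT	L	6	3.8	0
CTC	L	6	3.8	0
CTA	L	6	3.8	0
CTG	L	6	3.8	0
CCT	P	4	-1.6	0
CCC	P	4	-1.6	0
CCA	P	4	-1.6	0
CCG	P	4	-1.6	0
CAT	H	2	-3.2	0
CAC	H	2	-3.2	0
CAA	Q	2	-3.5	0
CAG	Q	2	-3.5	0
CGT	R	6	-4.5	0
CGC	R	6	-4.5	0
CGA	R	6	-4.5	0
CGG	R	6	-4.5	0
ATT	I	3	4.5	0
ATC	I	3	4.5	0
ATA	I	3	4.5	0
ATG	M	1	1.9	0
ACT	T	4	-0.7	0
ACC	T	4	-0.7	0
ACA	T	4	-0.7	0
ACG	T	4	-0.7	0
AAT	N	2	-3.5	0
AAC	N	2	-3.5	0
AAA	K	2	-3.9	0
AAG	K	2	-3.9	0
AGT	S	6	-0.8	0
AGC	S	6	-0.8	0
AGA	R	6	-4.5	0
AGG	R	6	-4.5	0
GTT	V	4	4.2	0
GTC	V	4	4.2	0
GTA	V	4	4.2	0
GTG	V	4	4.2	0
GCT	A	4	1.8	0
GCC	A	4	1.8	0
GCA	A	4	1.8	0
GCG	A	4	1.8	0
GAT	D	2	-3.5	0
GAC	D	2	-3.5	0
GAA	E	2	-3.5	0
GAG	E	2	-3.5	0
GGT	G	4	-0.4	0
GGC	G	4	-0.4	0
GGA	G	4	-0.4	0
GGG	G	4	-0.4	0
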