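# Synthetic stand-in CAI relative-adaptiveness table (E. coli-style).
# Constructed from the commonly cited E. coli translationally optimal
# codon set: the optimal codon of each degenerate family has w = 1.0 and
# every other family member w = 0.3. These are NOT the empirical
# Sharp & Li weights; swap in any two-column codon<TAB>w file to use a
# measured reference. ATG, TGG and stop codons are excluded from CAI.
codon	w
TTT	0.3
TTC	1.0
TTA	0.3
TTG	0.3
CTT	0.3
CTC	0.3
CTA	0.3
CTG	1.0
ATT	0.3
ATC	1.0
ATA	0.3
GTT	1.0
GTC	0.3
GTA	0.3
GTG	0.3
TCT	1.0
TCC	0.3
TCA	0.3
TCG	0.3
AGT	0.3
AGC	0.3
CCT	0.3
CCC	0.3
CCA	0.3
CCG	1.0
ACT	0.3
ACC	1.0
ACA	0.3
ACG	0.3
GCT	1.0
GCC	0.3
GCA	0.3
GCG	0.3
TAT	0.3
TAC	1.0
CAT	0.3
CAC	1.0
CAA	0.3
CAG	1.0
AAT	0.3
AAC	1.0
AAA	1.0
AAG	0.3
GAT	0.3
GAC	1.0
GAA	1.0
GAG	0.3
TGT	0.3
TGC	1.0
CGT	1.0
CGC	0.3
CGA	0.3
CGG	0.3
AGA	0.3
AGG	0.3
GGT	1.0
GGC	0.3
GGA	0.3
GGG	0.3
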