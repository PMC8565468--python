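codon	amino_acid	trna_family	degeneracy_class
AAA	Lys	K	twofold_purine
AAC	Asn	N	twofold_pyrimidine
AAG	Lys	K	twofold_purine
AAT	Asn	N	twofold_pyrimidine
ACA	Thr	T	fourfold
ACC	Thr	T	fourfold
ACG	Thr	T	fourfold
ACT	Thr	T	fourfold
AGA	Stop	-	-
AGC	Ser	S2	twofold_pyrimidine
AGG	Stop	-	-
AGT	Ser	S2	twofold_pyrimidine
ATA	Met	M	twofold_purine
ATC	Ile	I	twofold_pyrimidine
ATG	Met	M	twofold_purine
ATT	Ile	I	twofold_pyrimidine
CAA	Gln	Q	twofold_purine
CAC	His	H	twofold_pyrimidine
CAG	Gln	Q	twofold_purine
CAT	His	H	twofold_pyrimidine
CCA	Pro	P	fourfold
CCC	Pro	P	fourfold
CCG	Pro	P	fourfold
CCT	Pro	P	fourfold
CGA	Arg	R	fourfold
CGC	Arg	R	fourfold
CGG	Arg	R	fourfold
CGT	Arg	R	fourfold
CTA	Leu	L2	fourfold
CTC	Leu	L2	fourfold
CTG	Leu	L2	fourfold
CTT	Leu	L2	fourfold
GAA	Glu	E	twofold_purine
GAC	Asp	D	twofold_pyrimidine
GAG	Glu	E	twofold_purine
GAT	Asp	D	twofold_pyrimidine
GCA	Ala	A	fourfold
GCC	Ala	A	fourfold
GCG	Ala	A	fourfold
GCT	Ala	A	fourfold
GGA	Gly	G	fourfold
GGC	Gly	G	fourfold
GGG	Gly	G	fourfold
GGT	Gly	G	fourfold
GTA	Val	V	fourfold
GTC	Val	V	fourfold
GTG	Val	V	fourfold
GTT	Val	V	fourfold
TAA	Stop	-	-
TAC	Tyr	Y	twofold_pyrimidine
TAG	Stop	-	-
TAT	Tyr	Y	twofold_pyrimidine
TCA	Ser	S1	fourfold
TCC	Ser	S1	fourfold
TCG	Ser	S1	fourfold
TCT	Ser	S1	fourfold
TGA	Trp	W	twofold_purine
TGC	Cys	C	twofold_pyrimidine
TGG	Trp	W	twofold_purine
TGT	Cys	C	twofold_pyrimidine
TTA	Leu	L1	twofold_purine
TTC	Phe	F	twofold_pyrimidine
TTG	Leu	L1	twofold_purine
TTT	Phe	F	twofold_pyrimidine
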