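name	consensus	category	response
ABRE	ACGTG	hormone	ABA
CGTCA-motif	CGTCA	hormone	methyl-jasmonate
TGACG-motif	TGACG	hormone	methyl-jasmonate
TCA-element	CCATCTTTTT	hormone	salicylic-acid
P-box	CCTTTTG	hormone	gibberellin
GARE-motif	TCTGTTG	hormone	gibberellin
TATC-box	TATCCCA	hormone	gibberellin
TGA-element	AACGAC	hormone	auxin
AuxRR-core	GGTCCAT	hormone	auxin
ARE	AAACCA	stress	anaerobic-induction
MBS	CAACTG	stress	drought
LTR	CCGAAA	stress	low-temperature
TC-rich repeats	GTTTTCTTAC	stress	defense-and-stress
WUN-motif	AAATTACT	stress	wounding
W-box	TTGACC	stress	defense-and-stress
CAT-box	GCCACT	development	meristem-expression
O2-site	GATGACATGG	development	zein-metabolism
circadian	CAAAGATATC	development	circadian-control
GCN4_motif	TGAGTCA	development	endosperm-expression
RY-element	CATGCATG	development	seed-specific
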