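element	consensus_iupac	category
ABRE	ACGTGGC	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
TATC-box	TATCCCA	hormone
GARE-motif	TCTGTTG	hormone
TGA-element	AACGAC	hormone
AuxRR-core	GGTCCAT	hormone
TCA-element	CCATCTTTTT	hormone
G-box	CACGTG	growth_development
Box4	ATTAAT	growth_development
MRE	AACCTAA	growth_development
O2-site	GATGACATGG	growth_development
circadian	CAAAGATATC	growth_development
MSA-like	YCYAACGGYA	growth_development
MBS	CAACTG	stress
ARE	AAACCA	stress
LTR	CCGAAA	stress
GC-motif	CCCCCG	stress
TC-rich_repeats	ATTCTCTAAC	stress
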