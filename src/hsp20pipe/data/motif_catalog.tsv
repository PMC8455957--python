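motif_name	pattern	category	subtype
ABRE	ACGTG	hormone_related	abscisic_acid
CGTCA-motif	CGTCA	hormone_related	MeJA
TCACG-motif	TCACG	hormone_related	MeJA
AuxRR-core	GGTCCAT	hormone_related	auxin
TGA-element	AACGAC	hormone_related	auxin
P-box	CCTTTTG	hormone_related	gibberellin
TATC-box	TATCCCA	hormone_related	gibberellin
GARE-motif	TCTGTTG	hormone_related	gibberellin
TCA-element	CCATCTTTTT	hormone_related	salicylic_acid
HSE	NGAANNTTCNNGAAN	stress_responsive	heat
MBS	CAACTG	stress_responsive	drought
LTR	CCGAAA	stress_responsive	low_temperature
ARE	AAACCA	stress_responsive	defense_and_stress
TC-rich-repeats	ATTTTCTTCA	stress_responsive	defense_and_stress
WUN-motif	AAATTTCCT	stress_responsive	wound
Box-4	ATTAAT	stress_responsive	light
G-box	CACGTG	stress_responsive	light
GT1-motif	GGTTAA	stress_responsive	light
TCT-motif	TCTTAC	stress_responsive	light
I-box	GATAAGR	stress_responsive	light
CAT-box	GCCACT	development_related	meristem_expression
O2-site	GATGAYRTGR	development_related	metabolism_regulation
circadian	CAANNNNATC	development_related	circadian_control
MSA-like	TCCAACGG	development_related	cell_cycle
GCN4-motif	TGAGTCA	development_related	endosperm_expression
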