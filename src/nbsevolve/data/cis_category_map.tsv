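element_name	category	function_label
TCA-element	hormone-related	salicylic acid responsiveness
SARE	hormone-related	salicylic acid responsiveness
ABRE	hormone-related	abscisic acid responsiveness
ABRE3a	hormone-related	abscisic acid responsiveness
ABRE4	hormone-related	abscisic acid responsiveness
CGTCA-motif	hormone-related	MeJA responsiveness
TGACG-motif	hormone-related	MeJA responsiveness
GARE-motif	hormone-related	gibberellin responsiveness
P-box	hormone-related	gibberellin responsiveness
TATC-box	hormone-related	gibberellin responsiveness
TGA-element	hormone-related	auxin responsiveness
AuxRR-core	hormone-related	auxin responsiveness
ERE	hormone-related	ethylene responsiveness
TC-rich repeats	stress-responsive	defense and stress responsiveness
STRE	stress-responsive	defense and stress responsiveness
W box	stress-responsive	defense and stress responsiveness
WRE3	stress-responsive	defense and stress responsiveness
MBS	stress-responsive	drought responsiveness
DRE core	stress-responsive	drought responsiveness
MYB	stress-responsive	drought responsiveness
MYC	stress-responsive	drought responsiveness
LTR	stress-responsive	low temperature responsiveness
WUN-motif	stress-responsive	wound responsiveness
ARE	stress-responsive	anaerobic induction
GC-motif	stress-responsive	anoxic inducibility
CAT-box	plant growth	meristem expression
O2-site	plant growth	zein metabolism regulation
GCN4_motif	plant growth	endosperm expression
circadian	plant growth	circadian control
RY-element	plant growth	seed-specific regulation
HD-Zip 1	plant growth	differentiation of palisade mesophyll cells
MSA-like	plant growth	cell cycle regulation
AACA_motif	plant growth	endosperm-specific expression
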