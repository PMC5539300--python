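# Default two-level transposable-element taxonomy (synthetic stand-in).
# Covers the TE types analysed in the pipeline's figures and tables plus
# common RepeatMasker-style types; users may supply their own full table
# (the canonical catalogue has 68 types).
# n_types=40
te_type	te_class
Alu	SINE
MIR	SINE
FLAM	SINE
FRAM	SINE
Deu	SINE
tRNA	SINE
L1	LINE
L2	LINE
L3	LINE
CR1	LINE
RTE	LINE
Penelope	LINE
Dong-R4	LINE
I-Jockey	LINE
ERV1	LTR
ERV3	LTR
ERVK	LTR
ERVL	LTR
ERVL-MaLR	LTR
Endogenous Retrovirus	LTR
LTR Retrotransposon	LTR
Gypsy	LTR
Copia	LTR
DIRS	LTR
SAT	Satellite
Alpha	Satellite
Beta	Satellite
HSAT	Satellite
CER	Satellite
SVA	Retroposon
hAT	DNA
hAT-Charlie	DNA
hAT-Blackjack	DNA
hAT-Tip100	DNA
TcMar-Tigger	DNA
TcMar-Mariner	DNA
MuDR	DNA
PiggyBac	DNA
Merlin	DNA
Helitron	RC
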