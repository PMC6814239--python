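# Synthetic stand-in list of genes where loss of function is an established
# disease mechanism (feeds PVS1). One gene symbol per line; user-replaceable.
APC
ATM
BMPR1A
BRCA1
BRCA2
CDH1
CFTR
CHEK2
DMD
FBN1
KCNQ1
LDLR
MECP2
MLH1
MSH2
MSH6
MUTYH
MYBPC3
NF1
PALB2
PKD1
PMS2
PTEN
RB1
RYR1
SCN1A
SMAD4
STK11
TP53
TSC1
TSC2
VHL
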