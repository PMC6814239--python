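# Synthetic stand-in list of genes with a low rate of benign missense
# variation, where missense is a common disease mechanism (feeds PP2).
CACNA1A
FBN1
KCNH2
KCNQ1
MYH7
PTPN11
RYR1
SCN1A
SCN5A
SMAD4
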