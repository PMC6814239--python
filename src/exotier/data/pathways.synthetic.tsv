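# Synthetic offline snapshot of KEGG-style pathway -> gene sets used by the
# reverse pathway filter. Columns: pathway name, comma-separated gene symbols.
pathway	genes
Pathways in cancer	TP53,BRCA2,KRAS,APC,PTEN,RB1,MLH1,MSH2,SMAD4,STK11,VHL,CDH1
Mismatch repair	MLH1,MSH2,MSH6,PMS2
Homologous recombination	BRCA1,BRCA2,PALB2,RAD51,ATM
Colorectal cancer	APC,KRAS,TP53,SMAD4,MLH1,MSH2
Dilated cardiomyopathy	MYH7,TTN,MYBPC3,SCN5A
Calcium signaling pathway	CACNA1A,RYR1,KCNQ1
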