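# Synthetic snapshot of approximate coding lengths (bp) used only for the
# advisory long-gene warning in the by-gene report. Columns: gene, coding_bp.
gene	coding_bp
ACTB	1128
ALDH2	1554
APC	8532
BRCA1	5592
BRCA2	10257
CFTR	4443
KRAS	570
MLH1	2271
MUC16	43524
MYH7	5808
NEB	24765
OBSCN	23898
PTEN	1212
SCN1A	6030
SYNE1	26394
TP53	1182
TTN	107976
USH2A	15609
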