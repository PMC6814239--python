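# Synthetic stand-in table of known pathogenic amino-acid substitutions
# (feeds PS1/PM5). Columns: gene, protein_pos, ref_aa, alt_aa, cdna_change
# (optional; '.' when unknown). User-replaceable via the same layout.
gene	protein_pos	ref_aa	alt_aa	cdna_change
TP53	175	R	H	c.523C>T
TP53	273	R	H	c.818G>A
BRCA1	61	C	G	c.181T>G
KRAS	12	G	D	c.35G>A
MLH1	384	V	D	c.1151T>A
SCN1A	946	R	C	c.2836C>T
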