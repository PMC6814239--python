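# Synthetic stand-in snapshot of FLAGS (frequently mutated genes in public
# exomes), used only to warn on gene-burden entries.
AHNAK
AHNAK2
DNAH11
DNAH17
DST
FLG
HMCN1
HSPG2
LAMA5
MACF1
MUC16
MUC17
MUC5B
NEB
OBSCN
PLEC
SYNE1
SYNE2
TTN
USH2A
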