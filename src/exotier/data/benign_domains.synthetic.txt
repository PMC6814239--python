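# Synthetic stand-in list of protein-domain strings in which missense
# variation is common without established pathogenicity (excludes PM1).
Olfactory receptor
Keratin-associated protein
Zinc finger C2H2 superfamily
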