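# Synthetic stand-in list of genes where truncating variants are the only
# known disease mechanism, so missense is weak benign evidence (feeds BP1).
ASPM
NEB
OBSCN
PKHD1
TTN
WRN
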