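# Gene-level Mutation Significance Cutoffs for the aldosterone-driver panel.
# msc_cadd: CADD score cutoff; msc_pp2: PolyPhen-2 score cutoff.
# KCNJ5 has no published MSC row here (hotspot screening covers it before NGS),
# so it is deliberately absent; looking it up raises a defined error.
gene	msc_cadd	msc_pp2
ATP1A1	17.8	0.239
ATP2B3	3.313	0.239
CACNA1D	16.36	0.57
CACNA1H	0.001	0.001
CLCN2	0.001	0.02
CTNNB1	16.39	0.239
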