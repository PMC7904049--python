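id	label	vocabulary	description
MOD:00696	phosphorylated residue	PSI-MOD	A protein modification that effectively converts a residue to its phosphorylated form.
MOD:00046	O-phospho-L-serine	PSI-MOD	A protein modification that effectively converts an L-serine to O-phospho-L-serine.
MOD:00047	O-phospho-L-threonine	PSI-MOD	A protein modification that effectively converts an L-threonine to O-phospho-L-threonine.
MOD:00048	O4'-phospho-L-tyrosine	PSI-MOD	A protein modification that effectively converts an L-tyrosine to O4'-phospho-L-tyrosine.
MOD:00394	acetylated residue	PSI-MOD	A protein modification that effectively converts a residue to its acetylated form.
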