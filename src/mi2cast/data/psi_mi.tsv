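id	label	vocabulary	description
MI:2235	up-regulates	PSI-MI	The source entity positively affects the activity or quantity of the target entity.
MI:2236	up-regulates activity	PSI-MI	Positive regulation of the target's molecular activity.
MI:2237	up-regulates quantity	PSI-MI	Positive regulation of the target's abundance.
MI:2240	down-regulates	PSI-MI	The source entity negatively affects the activity or quantity of the target entity.
MI:2241	down-regulates activity	PSI-MI	Negative regulation of the target's molecular activity.
MI:2242	down-regulates quantity	PSI-MI	Negative regulation of the target's abundance.
MI:0217	phosphorylation reaction	PSI-MI	Reaction covalently adding a phosphate group to a molecule.
MI:0220	ubiquitination reaction	PSI-MI	Reaction covalently attaching ubiquitin to a target molecule.
MI:0407	direct interaction	PSI-MI	Interaction between molecules that are in direct contact.
MI:0326	protein	PSI-MI	A polypeptide chain interactor type.
MI:0328	small molecule	PSI-MI	A low molecular weight compound interactor type.
MI:0320	ribonucleic acid	PSI-MI	An RNA interactor type.
MI:0319	deoxyribonucleic acid	PSI-MI	A DNA interactor type.
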