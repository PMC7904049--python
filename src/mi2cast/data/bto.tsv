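id	label	vocabulary	description
BTO:0000567	HeLa cell	BRENDA Tissue Ontology	Human cervix carcinoma cell line.
BTO:0000093	MCF-7 cell	BRENDA Tissue Ontology	Human breast adenocarcinoma cell line.
BTO:0000759	liver	BRENDA Tissue Ontology	The large gland of vertebrates associated with digestion.
BTO:0000142	brain	BRENDA Tissue Ontology	The portion of the vertebrate central nervous system enclosed in the skull.
BTO:0000089	blood	BRENDA Tissue Ontology	The fluid circulating through the heart, arteries, capillaries and veins.
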