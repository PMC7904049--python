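id	label	vocabulary	description
RO:0002211	regulates	Relation Ontology	A process that modulates the frequency, rate or extent of another process.
RO:0002212	negatively regulates	Relation Ontology	A process that decreases the frequency, rate or extent of another process.
RO:0002213	positively regulates	Relation Ontology	A process that increases the frequency, rate or extent of another process.
RO:0002629	directly positively regulates	Relation Ontology	Positive regulation through direct physical contact.
RO:0002630	directly negatively regulates	Relation Ontology	Negative regulation through direct physical contact.
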