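id	label	vocabulary	description
CL:0000057	fibroblast	Cell Ontology	A connective tissue cell which secretes an extracellular matrix.
CL:0000084	T cell	Cell Ontology	A type of lymphocyte maturing in the thymus.
CL:0000236	B cell	Cell Ontology	A lymphocyte of B lineage capable of secreting immunoglobulin.
CL:0000182	hepatocyte	Cell Ontology	The main structural component of the liver.
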