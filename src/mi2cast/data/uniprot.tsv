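id	label	vocabulary	description
uniprot:P31750	AKT1_MOUSE	UniProt	RAC-alpha serine/threonine-protein kinase, Mus musculus.
uniprot:P31749	AKT1_HUMAN	UniProt	RAC-alpha serine/threonine-protein kinase, Homo sapiens.
uniprot:Q60823	AKT2_MOUSE	UniProt	RAC-beta serine/threonine-protein kinase, Mus musculus.
uniprot:P04049	RAF1_HUMAN	UniProt	RAF proto-oncogene serine/threonine-protein kinase, Homo sapiens.
uniprot:P28482	MK01_HUMAN	UniProt	Mitogen-activated protein kinase 1, Homo sapiens.
uniprot:P27361	MK03_HUMAN	UniProt	Mitogen-activated protein kinase 3, Homo sapiens.
uniprot:O43524	FOXO3_HUMAN	UniProt	Forkhead box protein O3, Homo sapiens.
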