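id	label	vocabulary	description
NCBITaxon:9606	Homo sapiens	NCBI Taxonomy	Human.
NCBITaxon:10090	Mus musculus	NCBI Taxonomy	House mouse.
NCBITaxon:10116	Rattus norvegicus	NCBI Taxonomy	Norway rat.
NCBITaxon:7227	Drosophila melanogaster	NCBI Taxonomy	Fruit fly.
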