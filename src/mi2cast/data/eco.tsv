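id	label	vocabulary	description
ECO:0000006	experimental evidence	ECO	Evidence resulting from a laboratory experiment.
ECO:0000269	experimental evidence used in manual assertion	ECO	Experimental evidence applied by a curator.
ECO:0000314	direct assay evidence used in manual assertion	ECO	Direct assay evidence applied by a curator.
ECO:0000315	mutant phenotype evidence used in manual assertion	ECO	Mutant phenotype evidence applied by a curator.
ECO:0000353	physical interaction evidence used in manual assertion	ECO	Physical interaction evidence applied by a curator.
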