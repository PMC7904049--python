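id	label	vocabulary	description
GO:0005634	nucleus	GO	A membrane-bounded organelle containing the chromosomes.
GO:0005737	cytoplasm	GO	The contents of a cell excluding the plasma membrane and nucleus.
GO:0005829	cytosol	GO	The part of the cytoplasm not contained in membrane-bounded organelles.
GO:0005886	plasma membrane	GO	The membrane surrounding a cell.
GO:0005739	mitochondrion	GO	A semiautonomous, self replicating organelle.
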