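#ID(s) interactor A	ID(s) interactor B	Alt. ID(s) interactor A	Alt. ID(s) interactor B	Alias(es) interactor A	Alias(es) interactor B	Interaction detection method(s)	Publication 1st author(s)	Publication Identifier(s)	Taxid interactor A	Taxid interactor B	Interaction type(s)	Source database(s)	Interaction identifier(s)	Confidence value(s)	Expansion method(s)	Biological role(s) interactor A	Biological role(s) interactor B	Experimental role(s) interactor A	Experimental role(s) interactor B	Type(s) interactor A	Type(s) interactor B	Xref(s) interactor A	Xref(s) interactor B	Interaction Xref(s)	Annotation(s) interactor A	Annotation(s) interactor B	Interaction annotation(s)	Host organism(s)	Interaction parameter(s)	Creation date	Update date	Checksum(s) interactor A	Checksum(s) interactor B	Interaction Checksum(s)	Negative	Feature(s) interactor A	Feature(s) interactor B	Stoichiometry(s) interactor A	Stoichiometry(s) interactor B	Identification method participant A	Identification method participant B	Biological effect of interactor A	Biological effect of interactor B	Causal regulatory mechanism	Causal statement
uniprot:P28482	uniprot:Q60823	-	-	uniprot:MK01_HUMAN(display_short)	uniprot:AKT2_MOUSE(display_short)	eco:"ECO:0000315"(mutant phenotype evidence used in manual assertion)	-	"pubmed:8812311"	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	false	-	-	-	-	-	-	-	-	-	ro:"RO:0002629"(directly positively regulates)
uniprot:P28482	uniprot:P31750	-	-	uniprot:MK01_HUMAN(display_short)	uniprot:AKT1_MOUSE(display_short)	eco:"ECO:0000315"(mutant phenotype evidence used in manual assertion)	-	"pubmed:3392436"	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	false	-	-	-	-	-	-	-	-	-	psi-mi:"MI:2242"(down-regulates quantity)
uniprot:P27361	uniprot:P31750	-	-	uniprot:MK03_HUMAN(display_short)	uniprot:AKT1_MOUSE(display_short)	eco:"ECO:0000353"(physical interaction evidence used in manual assertion)|eco:"ECO:0000269"(experimental evidence used in manual assertion)|eco:"ECO:0000314"(direct assay evidence used in manual assertion)	-	"pubmed:3184612"|"pubmed:2188277"	-	-	-	-	-	-	-	-	-	-	-	psi-mi:"MI:0328"(small molecule)	-	-	-	-	-	-	-	-	-	-	-	-	-	-	false	-	-	-	-	-	-	-	-	-	psi-mi:"MI:2237"(up-regulates quantity)
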