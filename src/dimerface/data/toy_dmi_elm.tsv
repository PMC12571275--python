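ELM identifier	Interaction Domain Id	Interaction Domain Description
LIG_TOY_PIP_1	PF02747	PCNA-clamp binding domain (toy)
LIG_TOY_PIP_1	PF00705	PCNA-clamp binding domain (toy)
LIG_TOY_AA_1	PF00069	Protein kinase domain (toy)
DOC_TOY_PRO_1	PF00071	Small GTPase fold (toy)
LIG_TOY_NTERM_1	PF00017	SH2-like module (toy)
LIG_TOY_CTERM_1	PF00595	PDZ-like module (toy)
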