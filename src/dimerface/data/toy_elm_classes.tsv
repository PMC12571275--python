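ELMIdentifier	Regex	Description
LIG_TOY_PIP_1	Q..[ILM]..[FY][FY]	PIP-box-like clamp-binding motif (toy)
LIG_TOY_AA_1	AA	Dialanine test motif with overlapping occurrences (toy)
DOC_TOY_PRO_1	P.P	Proline-flanked docking motif (toy)
LIG_TOY_NTERM_1	^M	Initiator-methionine anchored motif (toy)
LIG_TOY_CTERM_1	[ST].[VIL]$	C-terminal PDZ-binding motif (toy)
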