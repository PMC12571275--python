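PF00001	PF00002	HC
PF00004	PF00006	HC
PF00096	PF00096	MC
PF00069	PF00071	HC
PF00240	PF00240	HC
PF02747	PF00705	HC
NOTPFAM	PF00001	LC
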