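# toy 3did-dialect snapshot: two versioned Pfam accessions per row + extra column
PF00001.21	PF00002.20	1ABC
PF00002.20	PF00001.21	2DEF
PF00023.35	PF00554.25	3GHI
PF00023.35	PF16179.8	4JKL
PF00017.29	PF00017.29	5MNO
PF00069.30	PF00071.27	6PQR
PF00102.32	PF00069.30	7STU
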