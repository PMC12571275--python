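{
  "comment": "synthetic stand-in for a recorded InterPro Pfam-entry payload for a PCNA-like protein: two Pfam domains (sliding-clamp N- and C-terminal halves) plus one non-Pfam entry that must be ignored",
  "count": 3,
  "results": [
    {
      "metadata": {"accession": "PF00705", "name": "Proliferating cell nuclear antigen, N-terminal domain", "source_database": "pfam", "type": "domain"},
      "proteins": [
        {"accession": "p12004",
         "entry_protein_locations": [
           {"fragments": [{"start": 1, "end": 125, "dc-status": "CONTINUOUS"}], "model": "PF00705", "score": 1.1e-40}
         ]}
      ]
    },
    {
      "metadata": {"accession": "PF02747", "name": "Proliferating cell nuclear antigen, C-terminal domain", "source_database": "pfam", "type": "domain"},
      "proteins": [
        {"accession": "p12004",
         "entry_protein_locations": [
           {"fragments": [{"start": 135, "end": 255, "dc-status": "CONTINUOUS"}], "model": "PF02747", "score": 3.0e-44}
         ]}
      ]
    },
    {
      "metadata": {"accession": "IPR000308", "name": "not a Pfam entry", "source_database": "interpro", "type": "family"},
      "proteins": [
        {"accession": "p12004",
         "entry_protein_locations": [
           {"fragments": [{"start": 1, "end": 255, "dc-status": "CONTINUOUS"}]}
         ]}
      ]
    }
  ]
}
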