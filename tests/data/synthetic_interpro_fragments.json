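{
  "comment": "synthetic payload: one Pfam entry split into two fragments (discontinuous domain)",
  "count": 1,
  "results": [
    {
      "metadata": {"accession": "PF00069", "name": "Protein kinase domain", "source_database": "pfam", "type": "domain"},
      "proteins": [
        {"accession": "q00001",
         "entry_protein_locations": [
           {"fragments": [
              {"start": 10, "end": 60, "dc-status": "N_TERMINAL_DISC"},
              {"start": 80, "end": 140, "dc-status": "C_TERMINAL_DISC"}
           ]}
         ]}
      ]
    }
  ]
}
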