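{
  "comment": "Headline totals reported by the published 24-species holozoan membrane-proteome survey; inputs for recomputing its share arithmetic.",
  "total_membrane_proteins": 123014,
  "characterized_proteins": 105757,
  "lhca_subset_proteins": 90906,
  "receptor_proteins": 25862,
  "transporter_proteins": 22362,
  "enzyme_proteins": 18827,
  "lhca_proteome_total": 2283,
  "lhca_enzyme_proteins": 517,
  "lhca_transporter_proteins": 370,
  "lhca_receptor_proteins": 309,
  "lhca_clusters": 604,
  "level1_clusters": 6609,
  "level1_singlet_proteins": 7910
}
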