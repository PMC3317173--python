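{
  "clade_filter": null,
  "duplication_nodes": [
    9,
    16
  ],
  "n_duplications": 2,
  "n_multi_copy": 2,
  "n_species": 8,
  "n_tips": 10,
  "sister_paralog_pairs": [
    [
      "sp01",
      "g2",
      "g3"
    ],
    [
      "sp03",
      "g2",
      "g3"
    ]
  ]
}
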