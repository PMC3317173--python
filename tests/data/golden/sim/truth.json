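{
  "config": {
    "depth": 30,
    "dup_species": [
      "sp01",
      "sp03"
    ],
    "n_species": 8
  },
  "pair": {
    "architectures": {
      "coding_a": [
        [
          0,
          0.8748598928679363,
          10.0
        ],
        [
          182,
          0.8579486001264323,
          10.0
        ],
        [
          364,
          0.6275544669906046,
          10.0
        ],
        [
          546,
          0.5121226987735195,
          10.0
        ],
        [
          728,
          0.4948979284705413,
          10.0
        ],
        [
          910,
          0.4784087113578872,
          10.0
        ],
        [
          1092,
          0.6115534141178526,
          10.0
        ],
        [
          1274,
          0.6531837812705672,
          10.0
        ]
      ],
      "coding_b": [
        [
          0,
          0.8748598928679363,
          10.0
        ],
        [
          182,
          0.8579486001264323,
          10.0
        ],
        [
          364,
          0.6275544669906046,
          10.0
        ],
        [
          546,
          0.5121226987735195,
          10.0
        ],
        [
          728,
          0.4948979284705413,
          10.0
        ],
        [
          910,
          0.4784087113578872,
          10.0
        ],
        [
          1092,
          0.6115534141178526,
          10.0
        ],
        [
          1274,
          0.6531837812705672,
          10.0
        ]
      ],
      "promoter_a": [
        [
          -885,
          0.9280496606787028,
          10.0
        ],
        [
          -701,
          0.8429799831716354,
          10.0
        ],
        [
          -517,
          0.4576450329934143,
          10.0
        ],
        [
          -333,
          0.5101163994378578,
          10.0
        ],
        [
          -149,
          0.9114874117773832,
          10.0
        ]
      ],
      "promoter_b": [
        [
          -906,
          0.9968501984040747,
          10.0
        ],
        [
          -736,
          0.8548633434496271,
          10.0
        ],
        [
          -566,
          0.7355254606088139,
          10.0
        ],
        [
          -396,
          0.9922721033773194,
          10.0
        ],
        [
          -226,
          0.45071608876491925,
          10.0
        ],
        [
          -56,
          0.41214842370049115,
          10.0
        ]
      ]
    },
    "depth": 30,
    "jitter_sd": 10.0,
    "promoter_occupancy_boost": 1.5,
    "seed": 7,
    "share_coding": true,
    "share_promoter": false
  },
  "tree": {
    "dup_species": [
      "sp01",
      "sp03"
    ],
    "n_duplications": 2,
    "n_species": 8,
    "newick": "(((sp06|g1,(sp08|g1,sp05|g1)),(sp02|g1,(sp03|g2,sp03|g3))),((sp04|g1,sp07|g1),(sp01|g2,sp01|g3)));",
    "pairs": [
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
    ],
    "seed": 7
  }
}
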