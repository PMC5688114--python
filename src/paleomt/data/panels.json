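{
  "comment": "Editable multiplex SNP panel configuration. Each entry: rCRS coding position, reference-panel base, derived/diagnostic base, and the haplogroup the diagnostic base supports. Contents approximate the published GenoCoRe22 / H-PLEX17 / U-Plex / T-Plex assays; only the T-Plex SNPs (C12633A-T1, A11812G-T2) and the H1-defining G3010A are fixed by the source protocols, the rest is configuration.",
  "panels": {
    "GenoCoRe22": [
      {"position": 7028, "ref": "T", "alt": "C", "haplogroup": "H"},
      {"position": 14766, "ref": "T", "alt": "C", "haplogroup": "HV"},
      {"position": 4580, "ref": "G", "alt": "A", "haplogroup": "V"},
      {"position": 12308, "ref": "A", "alt": "G", "haplogroup": "U"},
      {"position": 9055, "ref": "G", "alt": "A", "haplogroup": "K"},
      {"position": 13708, "ref": "G", "alt": "A", "haplogroup": "J"},
      {"position": 13368, "ref": "G", "alt": "A", "haplogroup": "T"},
      {"position": 12705, "ref": "T", "alt": "C", "haplogroup": "R"},
      {"position": 10400, "ref": "C", "alt": "T", "haplogroup": "M"},
      {"position": 6371, "ref": "C", "alt": "T", "haplogroup": "X"},
      {"position": 8994, "ref": "G", "alt": "A", "haplogroup": "W"},
      {"position": 1719, "ref": "G", "alt": "A", "haplogroup": "N1a"},
      {"position": 3197, "ref": "T", "alt": "C", "haplogroup": "U5"},
      {"position": 10034, "ref": "T", "alt": "C", "haplogroup": "I"},
      {"position": 1811, "ref": "A", "alt": "G", "haplogroup": "U2"},
      {"position": 14139, "ref": "A", "alt": "G", "haplogroup": "U3"},
      {"position": 4646, "ref": "T", "alt": "C", "haplogroup": "U4"},
      {"position": 14793, "ref": "A", "alt": "G", "haplogroup": "U5a"},
      {"position": 7768, "ref": "A", "alt": "G", "haplogroup": "U5b"},
      {"position": 5178, "ref": "C", "alt": "A", "haplogroup": "D"},
      {"position": 663, "ref": "A", "alt": "G", "haplogroup": "A"},
      {"position": 4833, "ref": "A", "alt": "G", "haplogroup": "G"}
    ],
    "H-PLEX17": [
      {"position": 3010, "ref": "G", "alt": "A", "haplogroup": "H1"},
      {"position": 1438, "ref": "G", "alt": "A", "haplogroup": "H2"},
      {"position": 6776, "ref": "T", "alt": "C", "haplogroup": "H3"},
      {"position": 3992, "ref": "C", "alt": "T", "haplogroup": "H4"},
      {"position": 4336, "ref": "T", "alt": "C", "haplogroup": "H5"},
      {"position": 3915, "ref": "G", "alt": "A", "haplogroup": "H6"},
      {"position": 4793, "ref": "A", "alt": "G", "haplogroup": "H7"},
      {"position": 13101, "ref": "A", "alt": "C", "haplogroup": "H8"},
      {"position": 14470, "ref": "T", "alt": "C", "haplogroup": "H10"},
      {"position": 8448, "ref": "T", "alt": "C", "haplogroup": "H11"},
      {"position": 2259, "ref": "C", "alt": "T", "haplogroup": "H13"},
      {"position": 7645, "ref": "T", "alt": "C", "haplogroup": "H14"},
      {"position": 6253, "ref": "T", "alt": "C", "haplogroup": "H15"},
      {"position": 10394, "ref": "C", "alt": "T", "haplogroup": "H16"},
      {"position": 4452, "ref": "T", "alt": "C", "haplogroup": "H17"},
      {"position": 12127, "ref": "G", "alt": "A", "haplogroup": "H18"},
      {"position": 4659, "ref": "G", "alt": "A", "haplogroup": "H20"}
    ],
    "U-Plex": [
      {"position": 1811, "ref": "A", "alt": "G", "haplogroup": "U2"},
      {"position": 14139, "ref": "A", "alt": "G", "haplogroup": "U3"},
      {"position": 4646, "ref": "T", "alt": "C", "haplogroup": "U4"},
      {"position": 3197, "ref": "T", "alt": "C", "haplogroup": "U5"},
      {"position": 14793, "ref": "A", "alt": "G", "haplogroup": "U5a"},
      {"position": 7768, "ref": "A", "alt": "G", "haplogroup": "U5b"}
    ],
    "T-Plex": [
      {"position": 12633, "ref": "C", "alt": "A", "haplogroup": "T1"},
      {"position": 11812, "ref": "A", "alt": "G", "haplogroup": "T2"}
    ]
  }
}
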