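{
  "comment": "Phylotree-lite: a compact, config-replaceable mtDNA haplogroup tree with standard HVS-I motifs (rCRS-relative tokens) and coding-region diagnostics. Child motifs are cumulative with ancestors.",
  "nodes": [
    {"label": "ROOT", "parent": null, "hvs1": [], "coding": []},
    {"label": "L1b", "parent": "ROOT", "hvs1": ["16126C", "16187T", "16189C", "16223T", "16264T", "16270T", "16278T", "16311C"], "coding": []},
    {"label": "M", "parent": "ROOT", "hvs1": ["16223T"], "coding": [[10400, "T"]]},
    {"label": "N", "parent": "ROOT", "hvs1": ["16223T"], "coding": []},
    {"label": "N1a", "parent": "N", "hvs1": ["16147A", "16172C", "16248T", "16355T"], "coding": [[1719, "A"]]},
    {"label": "W", "parent": "N", "hvs1": ["16292T"], "coding": [[8994, "A"]]},
    {"label": "X", "parent": "N", "hvs1": ["16189C", "16278T"], "coding": [[6371, "T"]]},
    {"label": "R", "parent": "ROOT", "hvs1": [], "coding": [[12705, "C"]]},
    {"label": "HV", "parent": "R", "hvs1": [], "coding": [[14766, "C"]]},
    {"label": "H", "parent": "HV", "hvs1": [], "coding": [[7028, "C"]]},
    {"label": "H1", "parent": "H", "hvs1": [], "coding": [[3010, "A"]]},
    {"label": "H2", "parent": "H", "hvs1": [], "coding": [[1438, "A"]]},
    {"label": "H3", "parent": "H", "hvs1": [], "coding": [[6776, "C"]]},
    {"label": "H4", "parent": "H", "hvs1": [], "coding": [[3992, "T"]]},
    {"label": "H5", "parent": "H", "hvs1": [], "coding": [[4336, "C"]]},
    {"label": "H6", "parent": "H", "hvs1": [], "coding": [[3915, "A"]]},
    {"label": "H7", "parent": "H", "hvs1": [], "coding": [[4793, "G"]]},
    {"label": "H8", "parent": "H", "hvs1": [], "coding": [[13101, "C"]]},
    {"label": "H10", "parent": "H", "hvs1": [], "coding": [[14470, "C"]]},
    {"label": "H11", "parent": "H", "hvs1": [], "coding": [[8448, "C"]]},
    {"label": "H13", "parent": "H", "hvs1": [], "coding": [[2259, "T"]]},
    {"label": "H14", "parent": "H", "hvs1": [], "coding": [[7645, "C"]]},
    {"label": "H15", "parent": "H", "hvs1": [], "coding": [[6253, "C"]]},
    {"label": "H16", "parent": "H", "hvs1": [], "coding": [[10394, "T"]]},
    {"label": "H17", "parent": "H", "hvs1": [], "coding": [[4452, "C"]]},
    {"label": "H18", "parent": "H", "hvs1": [], "coding": [[12127, "A"]]},
    {"label": "H20", "parent": "H", "hvs1": [], "coding": [[4659, "A"]]},
    {"label": "V", "parent": "HV", "hvs1": ["16298C"], "coding": [[4580, "A"]]},
    {"label": "J", "parent": "R", "hvs1": ["16069T", "16126C"], "coding": [[13708, "A"]]},
    {"label": "T", "parent": "R", "hvs1": ["16126C", "16294T"], "coding": [[13368, "A"]]},
    {"label": "T1", "parent": "T", "hvs1": ["16163G", "16186T", "16189C"], "coding": [[12633, "A"]]},
    {"label": "T2", "parent": "T", "hvs1": ["16296T"], "coding": [[11812, "G"]]},
    {"label": "U", "parent": "R", "hvs1": [], "coding": [[12308, "G"]]},
    {"label": "U2", "parent": "U", "hvs1": ["16051G"], "coding": [[1811, "G"]]},
    {"label": "U3", "parent": "U", "hvs1": ["16343G"], "coding": [[14139, "G"]]},
    {"label": "U4", "parent": "U", "hvs1": ["16356C"], "coding": [[4646, "C"]]},
    {"label": "U5", "parent": "U", "hvs1": ["16270T"], "coding": [[3197, "C"]]},
    {"label": "U5a", "parent": "U5", "hvs1": ["16256T"], "coding": [[14793, "G"]]},
    {"label": "U5b", "parent": "U5", "hvs1": ["16189C"], "coding": [[7768, "G"]]},
    {"label": "U8", "parent": "U", "hvs1": ["16342C"], "coding": []},
    {"label": "K", "parent": "U8", "hvs1": ["16224C", "16311C"], "coding": [[9055, "A"]]}
  ]
}
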