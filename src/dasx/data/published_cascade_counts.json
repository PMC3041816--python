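{
  "description": "Published per-stage survivor counts of the original nine-stage exon-array extraction run (stage 0 = all summarized core probesets).",
  "stages": [
    {"stage": 0, "n_probesets": 221336, "n_genes": 16661},
    {"stage": 1, "n_probesets": 188374, "n_genes": 15753},
    {"stage": 2, "n_probesets": 185028, "n_genes": 15654},
    {"stage": 3, "n_probesets": 159552, "n_genes": 15238},
    {"stage": 4, "n_probesets": 102661, "n_genes": 8601},
    {"stage": 5, "n_probesets": 94780, "n_genes": 8541},
    {"stage": 6, "n_probesets": 1636, "n_genes": 948},
    {"stage": 7, "n_probesets": 1107, "n_genes": 805},
    {"stage": 8, "n_probesets": 309, "n_genes": 278},
    {"stage": 9, "n_probesets": 262, "n_genes": 236}
  ]
}
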