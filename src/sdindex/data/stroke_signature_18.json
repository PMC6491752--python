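{
  "stroke_enriched": [
    "Butyricimonas",
    "Parabacteroides",
    "Un Rikenellaceae",
    "Un Ruminococcaceae",
    "Oscillospira",
    "Bilophila",
    "Un Enterobacteriaceae"
  ],
  "control_enriched": [
    "Knoellia",
    "Prevotella",
    "Un Clostridiaceae",
    "Coprococcus",
    "Lachnospira",
    "Roseburia",
    "Fecalibacterium",
    "Un Erysipelotrichaceae",
    "Un Caulobacteraceae",
    "Un Bradyrhizobiaceae",
    "Haemophilus"
  ],
  "provenance": {
    "threshold": 0.1,
    "test": "wilcoxon-rank-sum + BH-FDR",
    "cohort": "published 104-patient / 90-control training cohort",
    "note": "packaged preset of the published 18-genus stroke dysbiosis signature"
  }
}
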