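{
  "survey": "Dictyocysta lepida, three regional populations; printed as group summaries only",
  "encoding_notes": "Each printed region row is a group summary over n loricae; it is encoded as n identical pseudo-loricae carrying the printed per-taxon mean cells. The table header labels per-taxon cells '% of total liths' but the values behave like mean lith counts (155 Calcidiscus liths x 124 pg = 19 220 pg, close to the printed 19 922 pg total); both readings are emitted by the pipeline, neither is asserted. Umbellosphaera cells are stored as mass_pg (no reference per-lith mass). Occurrence-only cells ('10 of 18') are annotations, not per-lorica observations.",
  "pseudo_loricae_note": "D01-D18 = Southern Ocean Time Series (n=18); I01-I05 = Indian Ocean (n=5); G01-G03 = Tonga (n=3)",
  "group_summaries": {
    "Southern Ocean Time Series": {
      "n": 18, "total_mean": 19922, "total_sd": 5287,
      "per_taxon": {"Calcidiscus": {"mean": 155, "sd": 46}}
    },
    "Indian Ocean": {
      "n": 5, "total_mean": 3248, "total_sd": 2299,
      "per_taxon": {"Emiliania": {"mean": 46, "sd": 63}, "Umbellosphaera": {"mean": 23, "sd": 15}, "Helicosphaera": {"mean": 17, "sd": 17}}
    },
    "Tonga": {
      "n": 3, "total_mean": 2428, "total_sd": 2141,
      "per_taxon": {"Emiliania": {"mean": 74, "sd": 69}, "Umbellosphaera": {"mean": 35, "sd": 17}}
    },
    "tropical_pooled": {
      "n": 8, "total_mean": 2428, "total_sd": 2141,
      "note": "the survey text gives the pooled tropical population (n = 8) as 2428 +/- 2141 pg per cell, numerically identical to the Tonga-only row; a weighted pool of the printed Indian Ocean and Tonga rows would give 2940.5 pg. The printed pooled value is retained as the authoritative input for the cold/warm ratio."
    }
  },
  "occurrences": {
    "Southern Ocean Time Series": {"Emiliania": [1, 18], "Helicosphaera": [10, 18]},
    "Indian Ocean": {"Gephyrocapsa": [2, 5], "Umbilicosphaera foliosa": [2, 5]},
    "Tonga": {"Calciosolenia": [1, 3], "Rhabdosphaera": [1, 3]}
  },
  "known_discrepancies": [
    {"lorica_id": "D01-D18", "printed_total": 19922, "component_sum": 19220, "note": "printed per-taxon columns are incomplete for all rows of this table; totals asserted from annotations only"},
    {"lorica_id": "I01-I05", "printed_total": 3248, "component_sum": 2587, "note": "46*4 + 23 + 17*140 = 2587"},
    {"lorica_id": "G01-G03", "printed_total": 2428, "component_sum": 331, "note": "74*4 + 35 = 331"}
  ]
}
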