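{
  "survey": "Codonellopsis pusilla, Southern Ocean Time Series station; heavily Calcidiscus-ballasted population",
  "encoding_notes": "Single printed summary row (n = 13) encoded as one pseudo-lorica carrying the printed per-taxon mean values, read as mean lith counts.",
  "pseudo_loricae": {"S-CAL": {"group": "Southern Ocean Time Series", "n": 13}},
  "group_summaries": {
    "Southern Ocean Time Series": {
      "n": 13, "total_mean": 10540, "total_sd": 3537,
      "per_taxon": {"Emiliania": {"mean": 50, "sd": 40}, "Calcidiscus": {"mean": 83, "sd": 30}}
    }
  },
  "occurrences": {
    "Southern Ocean Time Series": {
      "Gephyrocapsa oceanica": [1, 13], "Coronosphaera": [1, 13], "Nitzschia bicapitata": [1, 13]
    }
  },
  "known_discrepancies": [
    {"lorica_id": "S-CAL", "printed_total": 10540, "component_sum": 10492, "note": "50*4 + 83*124 = 10492; printed per-taxon columns are incomplete for this row"}
  ]
}
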