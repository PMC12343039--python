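{
  "survey": "Codonellopsis cf. soyai, Kerguelen Island Plateau; Emiliania lith cover (pg CaCO3/lorica) and diatom fragments (pg silica/lorica)",
  "encoding_notes": "Emiliania cells printed as pg are exact multiples of the 4 pg/lith reference mass and are stored as lith counts (e.g. 1488 pg -> 372 liths); diatom fragment cells are stored verbatim as mass_pg.",
  "printed_row_totals": {
    "K01": 1488, "K02": 891, "K03": 1044, "K04": 475, "K05": 552,
    "K06": 296, "K07": 180, "K08": 158, "K09": 111, "K10": 25, "K11": 35
  },
  "printed_emiliania_percent": {
    "K01": 100, "K02": 99, "K03": 92, "K04": 98, "K05": 96,
    "K06": 97, "K07": 64, "K08": 56, "K09": 79, "K10": 0, "K11": 0
  },
  "known_discrepancies": [
    {
      "lorica_id": "K07",
      "printed_total": 180,
      "component_sum": 182,
      "note": "printed components (116 + 2 + 25 + 32 + 7) sum to 182, not the printed 180; both values retained, neither authoritative"
    }
  ],
  "group_summaries": {
    "Kerguelen Island Plateau": {
      "n": 11,
      "total_mean": 477, "total_sd": 454,
      "per_taxon": {"Emiliania": {"mean": 445, "sd": 461}},
      "percent_mean": 73, "percent_sd": 36,
      "note": "printed percent mean 73 does not match recomputation from the printed percent cells (70.9); the sd 36 does match"
    }
  },
  "occurrences": {
    "Kerguelen Island Plateau": {
      "Fragilariopsis": [5, 11], "Pseudo-nitzschia": [4, 11],
      "Chaetoceros": [5, 11], "Thalassiothrix": [4, 11],
      "Coscinodiscus": [6, 11], "Eucampia": [2, 11]
    }
  }
}
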