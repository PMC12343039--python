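{
  "survey": "Codonellopsis pusilla, North Atlantic (Porcupine Abyssal Plain); lorica-type groups",
  "encoding_notes": "Each printed row is a lorica-type group summary, encoded here as one pseudo-lorica carrying the printed per-taxon mean values. The column header does not state whether cells are mean lith counts or pg; they are treated as counts because group arithmetic approximately supports that reading (stored with this provenance note, totals not asserted). Printed standard deviations with implausible formatting (19 +/- 312, 1228 +/- 3518) are retained verbatim below and excluded from assertions.",
  "pseudo_loricae": {
    "A-CAL": {"group": "Calcidiscus dominated-type", "n": 10},
    "A-COC": {"group": "Coccolithus dominated-type", "n": 5},
    "A-FPN": {"group": "F. pseudonana diatom-type", "n": 9},
    "A-OTH": {"group": "Others", "n": 11}
  },
  "group_summaries": {
    "Calcidiscus dominated-type": {
      "n": 10, "total_mean": 5008, "total_sd": 1305,
      "per_taxon": {"Emiliania": {"mean": 104, "sd": 33}, "Gephyrocapsa oceanica": {"mean": 31, "sd": 22}, "Calcidiscus": {"mean": 35, "sd": 11}, "Coronosphaera": {"mean": 14, "sd": 7}}
    },
    "Coccolithus dominated-type": {
      "n": 5, "total_mean": 6966, "total_sd": 1990,
      "per_taxon": {"Emiliania": {"mean": 81, "sd": 38}, "Gephyrocapsa oceanica": {"mean": 1, "sd": 1}, "Helicosphaera": {"mean": 3, "sd": 4}, "Coccolithus": {"mean": 40, "sd": 12}}
    },
    "F. pseudonana diatom-type": {
      "n": 9, "total_mean": 1228, "total_sd": 3518,
      "per_taxon": {"Emiliania": {"mean": 187, "sd": 344}, "Gephyrocapsa oceanica": {"mean": 19, "sd": 312}, "Calcidiscus": {"mean": 1, "sd": 31}, "Coronosphaera": {"mean": 8, "sd": 310}, "Fragilariopsis pseudonana": {"mean": 34, "sd": 35, "unit": "pg silica per lorica"}}
    },
    "Others": {
      "n": 11, "total_mean": 1276, "total_sd": 323,
      "per_taxon": {"Emiliania": {"mean": 213, "sd": 53}, "Gephyrocapsa oceanica": {"mean": 146, "sd": 13}, "Calcidiscus": {"mean": 13, "sd": 13}, "Coronosphaera": {"mean": 16, "sd": 10}}
    },
    "Total": {
      "n": 35, "total_mean": 2585, "total_sd": 2390,
      "per_taxon": {"Emiliania": {"mean": 170, "sd": 70}, "Gephyrocapsa oceanica": {"mean": 17, "sd": 16}, "Calcidiscus": {"mean": 7, "sd": 14}, "Coronosphaera": {"mean": 11, "sd": 10}}
    }
  },
  "occurrences": {
    "Calcidiscus dominated-type": {"Fragilariopsis pseudonana": [4, 11]},
    "Coccolithus dominated-type": {"Nitzschia bicapitata": [2, 5]},
    "Total": {"Umbellosphaera": [1, 35], "Helicosphaera": [1, 35], "Coccolithus": [3, 35], "diatoms (any)": [11, 35]}
  },
  "known_discrepancies": [
    {"lorica_id": "A-CAL", "printed_total": 5008, "component_sum": 5020, "note": "counts x reference masses: 104*4 + 31*4 + 35*124 + 14*10 = 5020"},
    {"lorica_id": "A-COC", "printed_total": 6966, "component_sum": 6828, "note": "81*4 + 1*4 + 3*140 + 40*152 = 6828"},
    {"lorica_id": "A-FPN", "printed_total": 1228, "component_sum": 1062, "note": "748 + 76 + 124 + 80 + 34 pg silica = 1062; sd column formatting also implausible"},
    {"lorica_id": "A-OTH", "printed_total": 1276, "component_sum": 3208, "note": "count reading clearly fails for this row (852 + 584 + 1612 + 160 = 3208); cell semantics unresolved"}
  ]
}
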