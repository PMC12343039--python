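{
  "survey": "Codonella galea, Tonga (n = 9 loricae) and Coral Sea (n = 1); per-lorica pg CaCO3",
  "encoding_notes": "Printed per-taxon pg values are stored as lith counts where they are exact multiples of the reference per-lith mass (e.g. Emiliania 88 pg -> 22 liths) and as mass_pg otherwise. Umbellosphaera and Calciosolenia have no reference mass and are always mass_pg.",
  "printed_row_totals": {
    "T01": 932, "T02": 1058, "T03": 704, "T04": 2869, "T05": 2190,
    "T06": 1216, "T07": 1366, "T08": 594, "T09": 885, "C01": 1472
  },
  "known_discrepancies": [
    {"lorica_id": "T02", "printed_total": 1058, "component_sum": 886, "note": "172 + 504 + 90 + 120 = 886, not 1058"},
    {"lorica_id": "T03", "printed_total": 704, "component_sum": 713, "note": "121 + 12 + 190 + 390 = 713, not 704"},
    {"lorica_id": "C01", "printed_total": 1472, "component_sum": 1478, "note": "88 + 400 + 880 + 88 + 22 = 1478, not 1472"}
  ],
  "group_summaries": {
    "Tonga": {
      "n": 9, "total_mean": 1312, "total_sd": 706,
      "per_taxon": {
        "Emiliania": {"mean": 366, "sd": 672, "note": "column recomputes to mean 300; stored verbatim, not asserted"},
        "Umbilicosphaera": {"mean": 330, "sd": 233, "note": "column recomputes to mean 340.6; stored verbatim, not asserted"},
        "Syracosphaera": {"mean": 80, "sd": 56, "note": "column recomputes to mean 71.7; stored verbatim, not asserted"},
        "Rhabdosphaera": {"mean": 413, "sd": 432}
      }
    },
    "Coral Sea": {"n": 1, "total_mean": 1472, "total_sd": 0}
  },
  "occurrences": {
    "Tonga": {
      "Calcidiscus": [1, 9], "Calciosolenia": [1, 9], "Florisphaera": [2, 9],
      "Gladiolithus": [0, 9], "Umbellosphaera": [2, 9]
    }
  }
}
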