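lorica_id,tintinnid_taxon,locality,region_class,oral_diameter_um,bowl_length_um
S-CAL,Codonellopsis pusilla,Southern Ocean Time Series,polar,18.5,35.5
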