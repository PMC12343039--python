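lorica_id,tintinnid_taxon,locality,region_class,oral_diameter_um,bowl_length_um
A-CAL,Codonellopsis pusilla,North Atlantic,temperate,20.5,
A-COC,Codonellopsis pusilla,North Atlantic,temperate,20.5,
A-FPN,Codonellopsis pusilla,North Atlantic,temperate,20.5,
A-OTH,Codonellopsis pusilla,North Atlantic,temperate,20.5,
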