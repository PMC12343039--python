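lorica_id,particle_taxon,particle_kind,quantity_type,quantity
S-CAL,Emiliania,coccolith,count,50
S-CAL,Calcidiscus,coccolith,count,83
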