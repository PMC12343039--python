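lorica_id,particle_taxon,particle_kind,quantity_type,quantity
A-CAL,Emiliania,coccolith,count,104
A-CAL,Gephyrocapsa oceanica,coccolith,count,31
A-CAL,Calcidiscus,coccolith,count,35
A-CAL,Coronosphaera,coccolith,count,14
A-COC,Emiliania,coccolith,count,81
A-COC,Gephyrocapsa oceanica,coccolith,count,1
A-COC,Helicosphaera,coccolith,count,3
A-COC,Coccolithus,coccolith,count,40
A-FPN,Emiliania,coccolith,count,187
A-FPN,Gephyrocapsa oceanica,coccolith,count,19
A-FPN,Calcidiscus,coccolith,count,1
A-FPN,Coronosphaera,coccolith,count,8
A-FPN,Fragilariopsis pseudonana,diatom_cell,mass_pg,34
A-OTH,Emiliania,coccolith,count,213
A-OTH,Gephyrocapsa oceanica,coccolith,count,146
A-OTH,Calcidiscus,coccolith,count,13
A-OTH,Coronosphaera,coccolith,count,16
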