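lorica_id,particle_taxon,particle_kind,quantity_type,quantity
D01,Calcidiscus,coccolith,count,155
D02,Calcidiscus,coccolith,count,155
D03,Calcidiscus,coccolith,count,155
D04,Calcidiscus,coccolith,count,155
D05,Calcidiscus,coccolith,count,155
D06,Calcidiscus,coccolith,count,155
D07,Calcidiscus,coccolith,count,155
D08,Calcidiscus,coccolith,count,155
D09,Calcidiscus,coccolith,count,155
D10,Calcidiscus,coccolith,count,155
D11,Calcidiscus,coccolith,count,155
D12,Calcidiscus,coccolith,count,155
D13,Calcidiscus,coccolith,count,155
D14,Calcidiscus,coccolith,count,155
D15,Calcidiscus,coccolith,count,155
D16,Calcidiscus,coccolith,count,155
D17,Calcidiscus,coccolith,count,155
D18,Calcidiscus,coccolith,count,155
I01,Emiliania,coccolith,count,46
I01,Umbellosphaera,coccolith,mass_pg,23
I01,Helicosphaera,coccolith,count,17
I02,Emiliania,coccolith,count,46
I02,Umbellosphaera,coccolith,mass_pg,23
I02,Helicosphaera,coccolith,count,17
I03,Emiliania,coccolith,count,46
I03,Umbellosphaera,coccolith,mass_pg,23
I03,Helicosphaera,coccolith,count,17
I04,Emiliania,coccolith,count,46
I04,Umbellosphaera,coccolith,mass_pg,23
I04,Helicosphaera,coccolith,count,17
I05,Emiliania,coccolith,count,46
I05,Umbellosphaera,coccolith,mass_pg,23
I05,Helicosphaera,coccolith,count,17
G01,Emiliania,coccolith,count,74
G01,Umbellosphaera,coccolith,mass_pg,35
G02,Emiliania,coccolith,count,74
G02,Umbellosphaera,coccolith,mass_pg,35
G03,Emiliania,coccolith,count,74
G03,Umbellosphaera,coccolith,mass_pg,35
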