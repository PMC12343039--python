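lorica_id,particle_taxon,particle_kind,quantity_type,quantity
T01,Emiliania,coccolith,count,22
T01,Florisphaera,coccolith,count,14
T01,Umbilicosphaera,coccolith,mass_pg,184
T01,Syracosphaera,coccolith,count,2
T01,Rhabdosphaera,coccolith,count,6
T02,Emiliania,coccolith,count,43
T02,Umbilicosphaera,coccolith,mass_pg,504
T02,Syracosphaera,coccolith,count,9
T02,Rhabdosphaera,coccolith,count,2
T03,Umbilicosphaera,coccolith,mass_pg,121
T03,Umbellosphaera,coccolith,mass_pg,12
T03,Syracosphaera,coccolith,count,19
T03,Rhabdosphaera,coccolith,mass_pg,390
T04,Emiliania,coccolith,count,500
T04,Calcidiscus,coccolith,count,7
T05,Umbilicosphaera,coccolith,count,40
T05,Syracosphaera,coccolith,count,5
T05,Rhabdosphaera,coccolith,count,25
T06,Emiliania,coccolith,count,24
T06,Florisphaera,coccolith,count,10
T06,Umbilicosphaera,coccolith,count,26
T06,Umbellosphaera,coccolith,mass_pg,144
T06,Syracosphaera,coccolith,count,6
T06,Rhabdosphaera,coccolith,count,5
T07,Calciosolenia,coccolith,mass_pg,16
T07,Umbilicosphaera,coccolith,mass_pg,680
T07,Syracosphaera,coccolith,count,1
T07,Rhabdosphaera,coccolith,count,11
T08,Emiliania,coccolith,count,62
T08,Umbilicosphaera,coccolith,count,16
T08,Syracosphaera,coccolith,count,9
T09,Emiliania,coccolith,count,24
T09,Umbilicosphaera,coccolith,mass_pg,264
T09,Syracosphaera,coccolith,mass_pg,135
T09,Rhabdosphaera,coccolith,mass_pg,390
C01,Emiliania,coccolith,count,22
C01,Florisphaera,coccolith,count,20
C01,Gladiolithus,coccolith,count,220
C01,Umbilicosphaera,coccolith,mass_pg,88
C01,Umbellosphaera,coccolith,mass_pg,22
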