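lorica_id,particle_taxon,particle_kind,quantity_type,quantity
K01,Emiliania,coccolith,count,372
K02,Emiliania,coccolith,count,220
K02,Fragilariopsis,diatom_fragment,mass_pg,5
K02,Pseudo-nitzschia,diatom_fragment,mass_pg,0.7
K02,Thalassiothrix,diatom_fragment,mass_pg,5.6
K03,Emiliania,coccolith,count,240
K03,Coscinodiscus,diatom_fragment,mass_pg,84
K04,Emiliania,coccolith,count,116
K04,Fragilariopsis,diatom_fragment,mass_pg,2
K04,Pseudo-nitzschia,diatom_fragment,mass_pg,1
K04,Thalassiothrix,diatom_fragment,mass_pg,8
K05,Emiliania,coccolith,count,132
K05,Chaetoceros,diatom_fragment,mass_pg,13
K05,Coscinodiscus,diatom_fragment,mass_pg,11
K06,Emiliania,coccolith,count,72
K06,Fragilariopsis,diatom_fragment,mass_pg,5
K06,Pseudo-nitzschia,diatom_fragment,mass_pg,1
K06,Chaetoceros,diatom_fragment,mass_pg,2
K07,Emiliania,coccolith,count,29
K07,Fragilariopsis,diatom_fragment,mass_pg,2
K07,Thalassiothrix,diatom_fragment,mass_pg,25
K07,Coscinodiscus,diatom_fragment,mass_pg,32
K07,Eucampia,diatom_fragment,mass_pg,7
K08,Emiliania,coccolith,count,22
K08,Thalassiothrix,diatom_fragment,mass_pg,11
K08,Coscinodiscus,diatom_fragment,mass_pg,52
K08,Eucampia,diatom_fragment,mass_pg,7
K09,Emiliania,coccolith,count,22
K09,Chaetoceros,diatom_fragment,mass_pg,13
K09,Coscinodiscus,diatom_fragment,mass_pg,10
K10,Chaetoceros,diatom_fragment,mass_pg,15
K10,Coscinodiscus,diatom_fragment,mass_pg,10
K11,Fragilariopsis,diatom_fragment,mass_pg,26
K11,Pseudo-nitzschia,diatom_fragment,mass_pg,2
K11,Chaetoceros,diatom_fragment,mass_pg,7
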