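lorica_id,tintinnid_taxon,locality,region_class,oral_diameter_um,bowl_length_um
K01,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K02,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K03,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K04,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K05,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K06,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K07,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K08,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K09,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K10,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
K11,Codonellopsis cf. soyai,Kerguelen Island Plateau,polar,22.5,
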