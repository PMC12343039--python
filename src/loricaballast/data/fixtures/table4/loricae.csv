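lorica_id,tintinnid_taxon,locality,region_class,oral_diameter_um,bowl_length_um
T01,Codonella galea,Tonga,tropical,51,77
T02,Codonella galea,Tonga,tropical,51,77
T03,Codonella galea,Tonga,tropical,51,77
T04,Codonella galea,Tonga,tropical,51,77
T05,Codonella galea,Tonga,tropical,51,77
T06,Codonella galea,Tonga,tropical,51,77
T07,Codonella galea,Tonga,tropical,51,77
T08,Codonella galea,Tonga,tropical,51,77
T09,Codonella galea,Tonga,tropical,51,77
C01,Codonella galea,Coral Sea,tropical,51,77
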