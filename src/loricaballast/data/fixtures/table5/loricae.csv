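lorica_id,tintinnid_taxon,locality,region_class,oral_diameter_um,bowl_length_um
D01,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D02,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D03,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D04,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D05,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D06,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D07,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D08,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D09,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D10,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D11,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D12,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D13,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D14,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D15,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D16,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D17,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
D18,Dictyocysta lepida,Southern Ocean Time Series,polar,38,
I01,Dictyocysta lepida,Indian Ocean,tropical,38,
I02,Dictyocysta lepida,Indian Ocean,tropical,38,
I03,Dictyocysta lepida,Indian Ocean,tropical,38,
I04,Dictyocysta lepida,Indian Ocean,tropical,38,
I05,Dictyocysta lepida,Indian Ocean,tropical,38,
G01,Dictyocysta lepida,Tonga,tropical,38,
G02,Dictyocysta lepida,Tonga,tropical,38,
G03,Dictyocysta lepida,Tonga,tropical,38,
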