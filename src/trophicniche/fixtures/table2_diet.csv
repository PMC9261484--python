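taxon,category,habitat_origin,pctFO,pctN,pctW,pct_iri_slack,pct_iri_wimereux,pct_iri_liane,pct_iri_canche,pct_iri_authie,pct_iri_somme,pct_iri_total
Arenicola marina,Polychaeta,M,1.06,0.06,0.13,,,,0.10,,,0.01
Hediste diversicolor,Polychaeta,MBF,6.38,4.05,4.72,0.68,0.67,,,0.26,29.62,2.43
Argyroneta aquatica,Arachnida,F,2.13,0.17,0.03,,1.31,,,,,0.02
Dolomedes sp.,Arachnida,F,1.06,0.28,0.05,1.36,,,,,,0.02
Haliplidea larvae,Insecta,F,3.19,0.50,0.01,0.25,,0.41,,,,0.07
Calliphoridae larvae,Insecta,F,1.06,1.61,0.09,,5.98,,,,,0.08
Chironomidea larvae,Insecta,F,8.51,2.16,0.32,,7.89,1.52,0.03,,0.42,0.92
Chironomidea pupae,Insecta,F,4.26,0.44,0.06,1.02,,0.36,,,,0.09
Unid. Tipulidea,Insecta,F,1.06,0.06,<0.01,,,,,0.03,,<0.01
Corixa sp.,Insecta,F,3.19,2.05,0.14,18.58,,0.03,,,,0.30
Lepidoptera larvae,Insecta,F,1.06,0.17,0.09,,0.76,,,,,0.01
Crambidea larvae,Insecta,F,1.06,0.06,0.01,,0.22,,,,,<0.01
Tettigonia sp.,Insecta,T,1.06,0.06,0.05,,0.29,,,,,0.01
Unid. Taeniopterygidea,Insecta,F,1.06,0.06,<0.01,,,,0.03,,,<0.01
Trichoptera larvae,Insecta,F,1.06,0.06,0.01,,,0.03,,,,<0.01
Limnephilidea larvae,Insecta,F,1.06,0.22,0.05,,0.90,,,,,0.01
Insecta eggs,Insecta,F,1.06,2.77,0.01,,,,,,6.59,0.13
Corophium volutator,Malacostraca,M,1.06,0.50,0.04,,,,,,1.24,0.02
Gammarus zaddachi,Malacostraca,MB,26.6,23.95,8.85,2.92,0.93,,60.34,80.09,5.30,37.84
Carcinus maenas,Malacostraca,M,26.6,2.94,8.96,9.79,,0.56,9.66,15.65,34.96,13.73
Crangon crangon,Malacostraca,M,7.45,1.05,3.71,1.07,,,6.37,0.97,,1.54
Palaemon elegans,Malacostraca,M,3.19,0.44,3.98,,,,,0.14,12.19,0.61
Gnathia sp.,Malacostraca,MB,2.13,0.11,<0.01,,,,,,0.53,0.01
Unid. Actinopterygians,Actinopterygii,,3.19,0.17,0.37,,,,,0.38,0.30,0.07
Anguilla anguilla,Actinopterygii,MBF,10.64,2.99,37.72,,30.19,66.88,1.37,,6.86,18.79
Sprattus sprattus,Actinopterygii,MB,1.06,0.39,0.80,,,,0.65,,,0.05
Gasterosteus aculeatus,Actinopterygii,MBF,1.06,0.06,0.41,,,0.26,,,,0.02
Pomatoschistus microps,Actinopterygii,MBF,12.77,2.27,9.50,22.40,0.95,1.19,4.81,2.47,0.71,6.52
Platichthys flesus,Actinopterygii,MBF,22.34,4.77,9.63,41.92,49.89,1.50,16.64,,1.13,13.95
Eggs,Actinopterygii,,3.19,1.66,0.03,,,1.48,,,0.13,0.23
Limecola balthica,Bivalvia,M,3.19,0.17,0.01,,,0.25,,,,0.02
Stenophysa marmorata,Gastropoda,F,1.06,43.79,10.23,,,25.54,,,,2.48
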