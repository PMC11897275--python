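victim,dosing,observed_aucr,predicted_aucr_static,predicted_aucr_pbpk,printed_ratio_static,printed_ratio_pbpk
Abiraterone,"1,000 mg, SD",0.42,0.04,0.22,0.08,0.51
Apixaban,"10 mg, SD",0.47,1.00,1.00,2.13,2.13
Apremilast,"30 mg, SD",0.28,0.04,0.22,0.14,0.78
Axitinib,"5 mg, SD",0.21,0.02,0.17,0.10,0.83
Baricitinib,"10 mg, SD",0.66,1.00,1.00,1.53,1.53
Bosutinib,"500 mg, SD",0.06,0.01,0.07,0.23,1.15
Crizotinib,"250 mg, SD",0.18,0.02,0.11,0.12,0.62
Edoxaban,"60 mg, SD",0.66,1.00,1.00,1.52,1.52
Flibanserin,"100 mg, SD",0.05,0.01,0.09,0.28,1.80
Fostamatinib,"150 mg, SD",0.25,0.10,0.34,0.40,1.35
Ibrutinib,"560 mg, SD",0.10,0.05,0.07,0.49,0.72
Lenvatinib,"24 mg, SD",0.91,1.00,1.00,1.10,1.10
Macitentan,"10 mg, QD",0.21,0.01,0.07,0.05,0.32
Nintedanib,"150 mg, SD",0.50,0.10,0.26,0.20,0.52
Ospemifene,"60 mg, SD",0.41,0.05,0.27,0.12,0.66
Panobinostat,"20 mg, SD",0.35,0.01,0.18,0.03,0.51
Ponatinib,"45 mg, SD",0.41,0.02,0.22,0.05,0.54
Roflumilast,"500 ug, SD",0.19,0.11,0.33,0.58,1.72
Rolapitant,"180 mg, SD",0.17,0.01,0.19,0.06,1.14
Ruxolitinib,"50 mg, SD",0.29,0.05,0.34,0.17,1.18
Sonidegib,"800 mg, SD",0.21,0.02,0.18,0.10,0.88
Tasimelteon,"20 mg, SD",0.11,0.02,0.15,0.17,1.35
Telaprevir,"750 mg, SD",0.08,0.01,0.16,0.15,2.03
Tofacitinib,"30 mg, SD",0.16,0.02,0.25,0.13,1.55
Venetoclax,"200 mg, SD",0.29,0.02,0.24,0.05,0.82
Vorapaxar,"20 mg, QD",1.08,0.11,0.80,0.10,0.74
Fedratinib,"500 mg, SD",0.19,0.02,0.08,0.08,0.42
Istradefylline,"40 mg, SD",0.21,0.01,0.20,0.06,0.96
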