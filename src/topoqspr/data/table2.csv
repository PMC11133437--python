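drug,M1,M2,H,F,SS,ReZG2,ReZG3
Sulfadiazine,86,97,7.719,228,18.787,19.7976,490
Dorzolamide,104,125,7.9905,310,21.2002,22.9595,704
Meloxicam,226,153,10.2381,350,26.7589,29.1286,830
Sulphadoxine,107,128,7.8714,349,21.4299,23.3286,736
Meticrane,94,111,7.0714,282,19.0382,20.5119,618
Famotidine,94,99,8.6333,250,20.2951,20.7833,478
Dabrafenib,192,229,15.4381,538,40.5236,43.8619,1228
Diuril,91,102,7.2857,267,18.6588,19.631,544
Daranide,84,96,6.2381,260,16.5485,17.5286,540
Metahydrin,104,122,7.8714,310,21.0951,22.6619,674
Sulfapyridine,86,97,7.7190,228,18.787,19.7976,490
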