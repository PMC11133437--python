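drug,polarizability,complexity,boiling_point,molecular_weight,molar_volume,flash_point
Sulfadiazine,25,327,512.6,250.28,167.3,263.8
Dorzolamide,29.9,534,575.8,324.4,211,302
Meloxicam,34.1,628,520.9,351.4,219.6,268.8
Sulphadoxine,30.1,420,522.8,310.33,215.3,270
Meticrane,25.6,485,549.1,275.3,188.1,285.9
Famotidine,31.3,469,662.4,337.5,183.6,354.4
Dabrafenib,50.5,817,653.7,519.6,359.9,349.2
Diuril,24.5,532,608.8,295.7,144,322
Daranide,24.3,452,590.5,305.2,171.2,310.9
Metahydrin,30.5,571,631.3,380.7,217.7,335.6
Sulfapyridine,25.9,331,473.5,249.29,174.1,240.2
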