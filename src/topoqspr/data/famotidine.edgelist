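# Famotidine — 3-[({2-[(diaminomethylidene)amino]-1,3-thiazol-4-yl}methyl)-
# sulfanyl]-N'-sulfamoylpropanimidamide. 20 heavy atoms, 20 bonds.
# Guanidine C1(N2)(N3)=N1 on thiazole CA; thiazole ring S1-CA-NB-CC-CD;
# chain CC-C5-S2-C6-C7 to amidine C8(N5)=N6; sulfamoyl S3(O1,O2)N7 on N6.
CA N1
N1 C1
C1 N2
C1 N3
S1 CA
CA NB
NB CC
CC CD
CD S1
CC C5
C5 S2
S2 C6
C6 C7
C7 C8
C8 N5
C8 N6
N6 S3
S3 O1
S3 O2
S3 N7
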