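# Daranide (dichlorphenamide) — 4,5-dichlorobenzene-1,3-disulfonamide.
# 16 heavy atoms, 16 bonds.
# Benzene C1..C6; sulfamoyl S1(O1,O2)N1 on C1 and S2(O3,O4)N2 on C3;
# CL1 on C4, CL2 on C5.
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
C1 S1
S1 O1
S1 O2
S1 N1
C3 S2
S2 O3
S2 O4
S2 N2
C4 CL1
C5 CL2
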