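# Meticrane — 6-methyl-3,4-dihydro-2H-1-benzothiopyran-7-sulfonamide
# 1,1-dioxide. 17 heavy atoms, 18 bonds.
# Benzene C4A-C5-C6-C7-C8-C8A fused with thiopyran C8A-S1-C2-C3-C4-C4A;
# S1 dioxide (O1, O2); C9 = 6-methyl; S2(O3,O4)N1 = 7-sulfonamide.
C4A C5
C5 C6
C6 C7
C7 C8
C8 C8A
C8A C4A
C8A S1
S1 C2
C2 C3
C3 C4
C4 C4A
S1 O1
S1 O2
C6 C9
C7 S2
S2 O3
S2 O4
S2 N1
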