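# Dorzolamide — 4-(ethylamino)-6-methyl-5,6-dihydro-4H-thieno[2,3-b]thiopyran-
# 2-sulfonamide 7,7-dioxide. 19 heavy atoms, 20 bonds.
# Thiophene ring S1-C2-C3-C3A-C7A fused with thiopyran C3A-C4-C5-C6-S7-C7A;
# S7 dioxide (O1, O2); C8 = 6-methyl; N1-C9-C10 = 4-ethylamino;
# S2(O3,O4)N2 = 2-sulfonamide.
S1 C2
C2 C3
C3 C3A
C3A C7A
C7A S1
C3A C4
C4 C5
C5 C6
C6 S7
S7 C7A
S7 O1
S7 O2
C6 C8
C4 N1
N1 C9
C9 C10
C2 S2
S2 O3
S2 O4
S2 N2
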