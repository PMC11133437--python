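# Diuril (chlorothiazide) — 6-chloro-4H-1,2,4-benzothiadiazine-7-sulfonamide
# 1,1-dioxide. 17 heavy atoms, 18 bonds.
# Benzene C4A-C5-C6-C7-C8-C8A fused with thiadiazine C8A-S1-N2-C3-N4-C4A;
# S1 dioxide (O1, O2); CL1 = 6-chloro; S2(O3,O4)N5 = 7-sulfonamide.
# NOTE: computed indices (M1=94, M2=111, F=282) disagree with the printed
# descriptor row (91, 102, 267); the source drawing is not recoverable.
# Shipped unverified.
C4A C5
C5 C6
C6 C7
C7 C8
C8 C8A
C8A C4A
C8A S1
S1 N2
N2 C3
C3 N4
N4 C4A
S1 O1
S1 O2
C6 CL1
C7 S2
S2 O3
S2 O4
S2 N5
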