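# Metahydrin (trichlormethiazide) — 6-chloro-3-(dichloromethyl)-3,4-dihydro-
# 2H-1,2,4-benzothiadiazine-7-sulfonamide 1,1-dioxide. 20 heavy atoms, 21 bonds.
# Diuril scaffold plus dichloromethyl C9(CL2,CL3) on ring C3.
# NOTE: computed indices (M1=110, F=330) disagree with the printed descriptor
# row (104, 310); the source drawing is not recoverable. Shipped unverified.
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
C3 C9
C9 CL2
C9 CL3
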