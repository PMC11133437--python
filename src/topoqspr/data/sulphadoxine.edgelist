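# Sulphadoxine — 4-amino-N-(5,6-dimethoxypyrimidin-4-yl)benzenesulfonamide
# 21 heavy atoms, 22 bonds.
# Aniline/sulfonamide part as in sulfadiazine; pyrimidine ring
# C7(-N2)-N3-C8-N4-C9-C10 with methoxy O3-C11 on C9 and O4-C12 on C10.
# NOTE: computed indices disagree with the printed descriptor row
# (e.g. F = 284 vs printed 349); the source drawing is not recoverable.
# Shipped unverified.
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
N1 C1
C4 S1
S1 O1
S1 O2
S1 N2
N2 C7
C7 N3
N3 C8
C8 N4
N4 C9
C9 C10
C10 C7
C9 O3
O3 C11
C10 O4
O4 C12
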