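# Sulfapyridine — 4-amino-N-(pyridin-2-yl)benzenesulfonamide
# Same scaffold as sulfadiazine with pyridin-2-yl in place of
# pyrimidin-2-yl: C7 ring position 2, N3 ring nitrogen, C8..C11 carbons.
# 17 heavy atoms, 18 bonds; degree partition identical to sulfadiazine.
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
C8 C9
C9 C10
C10 C11
C11 C7
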