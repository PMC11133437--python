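# Dabrafenib — N-{3-[5-(2-aminopyrimidin-4-yl)-2-tert-butyl-1,3-thiazol-4-yl]-
# 2-fluorophenyl}-2,6-difluorobenzenesulfonamide. 35 heavy atoms, 38 bonds.
# C1..C6 difluorophenyl (F1 on C2, F2 on C6), sulfonyl S1(O1,O2) on C1,
# sulfonamide N1 to central ring C7..C12 (F3 on C8, thiazolyl on C9);
# thiazole C13-N2-C14-S2-C15 (C13 = ring C4 on the phenyl, C15 = ring C5);
# tert-butyl C16(C17,C18,C19) on C14; aminopyrimidine ring
# C20-N3-C21-N4-C22-C23 on C15, with N5 = 2-amino on C21.
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
C2 F1
C6 F2
C1 S1
S1 O1
S1 O2
S1 N1
N1 C7
C7 C8
C8 C9
C9 C10
C10 C11
C11 C12
C12 C7
C8 F3
C9 C13
C13 N2
N2 C14
C14 S2
S2 C15
C15 C13
C14 C16
C16 C17
C16 C18
C16 C19
C15 C20
C20 N3
N3 C21
C21 N4
N4 C22
C22 C23
C23 C20
C21 N5
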