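# Meloxicam — 4-hydroxy-2-methyl-N-(5-methyl-1,3-thiazol-2-yl)-2H-1,2-
# benzothiazine-3-carboxamide 1,1-dioxide. 23 heavy atoms, 25 bonds.
# Benzene C4A-C5-C6-C7-C8-C8A fused with thiazine C8A-S1-N2-C3-C4-C4A;
# S1 dioxide (O1, O2); C9 = N2-methyl; O3 = 4-hydroxy;
# C10(=O4)-N3 carboxamide to thiazole C11; thiazole ring C11-N4-C12-C13-S2;
# C14 = thiazole 5-methyl.
# NOTE: computed M1 = 126 while the reference descriptor table prints 226
# (all six other indices agree); shipped unverified, never "corrected".
C4A C5
C5 C6
C6 C7
C7 C8
C8 C8A
C8A C4A
C8A S1
S1 N2
N2 C3
C3 C4
C4 C4A
S1 O1
S1 O2
N2 C9
C4 O3
C3 C10
C10 O4
C10 N3
N3 C11
C11 N4
N4 C12
C12 C13
C13 S2
S2 C11
C13 C14
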