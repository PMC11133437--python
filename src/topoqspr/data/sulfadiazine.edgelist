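# Sulfadiazine — 4-amino-N-(pyrimidin-2-yl)benzenesulfonamide
# Hydrogen-suppressed skeleton: 17 heavy atoms, 18 bonds.
# C1..C6 aniline ring (N1 = 4-amino nitrogen on C1, sulfonyl on C4);
# S1 sulfonyl sulfur with O1, O2; N2 sulfonamide nitrogen;
# C7 pyrimidine C2 flanked by ring nitrogens N3, N4; C8..C10 ring carbons.
# Every bond (incl. S=O) is one edge.
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
C10 N4
N4 C7
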