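# Reference covalent bond lengths (Angstrom) for H/C/N/O/F element pairs.
# Values are standard gas-phase equilibrium lengths as tabulated in common
# references (Allen et al., J. Chem. Soc. Perkin Trans. 2, 1987; CRC Handbook
# of Chemistry and Physics, "Bond Lengths in Crystalline Organic Compounds").
# margin is the +/- bracket (Angstrom) used for distance-based bond typing.
elem_a,elem_b,order,length,margin
H,H,1,0.74,0.1
H,C,1,1.09,0.1
H,N,1,1.01,0.1
H,O,1,0.96,0.1
H,F,1,0.92,0.1
C,C,1,1.54,0.1
C,C,2,1.34,0.1
C,C,3,1.20,0.1
C,N,1,1.47,0.1
C,N,2,1.27,0.1
C,N,3,1.15,0.1
C,O,1,1.43,0.1
C,O,2,1.21,0.1
C,O,3,1.13,0.1
C,F,1,1.35,0.1
N,N,1,1.45,0.1
N,N,2,1.25,0.1
N,N,3,1.10,0.1
N,O,1,1.40,0.1
N,O,2,1.21,0.1
N,F,1,1.36,0.1
O,O,1,1.48,0.1
O,O,2,1.21,0.1
O,F,1,1.42,0.1
F,F,1,1.42,0.1
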