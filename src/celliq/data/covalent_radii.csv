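# Single-bond covalent radii, Angstrom (P. Pyykko & M. Atsumi 2009)
# symbol,Z,radius_A
H,1,0.32
He,2,0.46
Li,3,1.33
Be,4,1.02
B,5,0.85
C,6,0.75
N,7,0.71
O,8,0.63
F,9,0.64
Ne,10,0.67
Na,11,1.55
Mg,12,1.39
Al,13,1.26
Si,14,1.16
P,15,1.11
S,16,1.03
Cl,17,0.99
Ar,18,0.96
K,19,1.96
Ca,20,1.71
Sc,21,1.48
Ti,22,1.36
V,23,1.34
Cr,24,1.22
Mn,25,1.19
Fe,26,1.16
Co,27,1.11
Ni,28,1.10
Cu,29,1.12
Zn,30,1.18
Ga,31,1.24
Ge,32,1.21
As,33,1.21
Se,34,1.16
Br,35,1.14
Kr,36,1.17
Ag,47,1.28
Sn,50,1.40
I,53,1.33
Pt,78,1.23
Au,79,1.24
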