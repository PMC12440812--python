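# Standard atomic weights, amu (IUPAC 2021 abridged)
# symbol,Z,mass_amu
H,1,1.008
He,2,4.0026
Li,3,6.94
Be,4,9.0122
B,5,10.81
C,6,12.011
N,7,14.007
O,8,15.999
F,9,18.998
Ne,10,20.180
Na,11,22.990
Mg,12,24.305
Al,13,26.982
Si,14,28.085
P,15,30.974
S,16,32.06
Cl,17,35.45
Ar,18,39.948
K,19,39.098
Ca,20,40.078
Sc,21,44.956
Ti,22,47.867
V,23,50.942
Cr,24,51.996
Mn,25,54.938
Fe,26,55.845
Co,27,58.933
Ni,28,58.693
Cu,29,63.546
Zn,30,65.38
Ga,31,69.723
Ge,32,72.630
As,33,74.922
Se,34,78.971
Br,35,79.904
Kr,36,83.798
Ag,47,107.87
Sn,50,118.71
I,53,126.90
Pt,78,195.08
Au,79,196.97
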