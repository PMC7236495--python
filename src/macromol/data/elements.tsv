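# symbol	standard_atomic_weight_Da
H	1.008
Li	6.94
B	10.81
C	12.011
N	14.007
O	15.999
F	18.998
Na	22.990
Mg	24.305
Si	28.085
P	30.974
S	32.06
Cl	35.45
K	39.098
Ca	40.078
Mn	54.938
Fe	55.845
Co	58.933
Ni	58.693
Cu	63.546
Zn	65.38
As	74.922
Se	78.971
Br	79.904
Mo	95.95
I	126.904
W	183.84
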