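# Coherent neutron scattering lengths, in Angstrom (1 fm = 1e-5 A).
# Bound coherent values; H and D to the precision used throughout.
H   -3.741e-5
D    6.667e-5
C    6.646e-5
N    9.360e-5
O    5.803e-5
P    5.130e-5
S    2.847e-5
Si   4.1491e-5
Na   3.630e-5
Cl   9.577e-5
K    3.670e-5
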