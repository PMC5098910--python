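# Synthetic stand-in residue frequencies emulating the qualitative
# character of a disordered-like protein dataset.
# Package constants; not measurements of any external database.
A	0.070
C	0.000
D	0.090
E	0.120
F	0.005
G	0.100
H	0.020
I	0.020
K	0.080
L	0.030
M	0.010
N	0.050
P	0.090
Q	0.060
R	0.040
S	0.110
T	0.070
V	0.030
W	0.000
Y	0.005
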