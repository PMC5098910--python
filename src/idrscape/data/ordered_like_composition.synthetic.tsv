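# Synthetic stand-in residue frequencies emulating the qualitative
# character of a ordered-like protein dataset.
# Package constants; not measurements of any external database.
A	0.080
C	0.020
D	0.050
E	0.060
F	0.045
G	0.070
H	0.022
I	0.060
K	0.060
L	0.100
M	0.024
N	0.044
P	0.045
Q	0.037
R	0.050
S	0.060
T	0.055
V	0.070
W	0.014
Y	0.034
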