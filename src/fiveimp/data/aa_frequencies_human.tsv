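amino_acid	frequency
A	0.070
R	0.056
N	0.036
D	0.047
C	0.023
Q	0.048
E	0.071
G	0.066
H	0.026
I	0.043
L	0.100
K	0.057
M	0.021
F	0.037
P	0.063
S	0.083
T	0.054
W	0.012
Y	0.027
V	0.060
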