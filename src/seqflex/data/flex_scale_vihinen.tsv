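# Per-residue intrinsic side-chain flexibility, in average normalized
# B-factor units (larger = more flexible).
# Source: Vihinen, Torkkila & Riikonen (1994), "Accuracy of protein
# flexibility predictions", Proteins 19:141-149; values as distributed by
# the ExPASy ProtScale "Normalized flexibility parameters (B-values),
# average" entry.
# Calibration state: raw (uncalibrated).
A	0.984
R	1.008
N	1.048
D	1.068
C	0.906
Q	1.037
E	1.094
G	1.031
H	0.950
I	0.927
L	0.935
K	1.102
M	0.952
F	0.915
P	1.049
S	1.046
T	0.997
W	0.904
Y	0.929
V	0.931
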