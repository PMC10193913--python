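# Per-residue disorder propensity used by the naive offline stand-in scorer.
# Heuristic composite table: the ordering follows the consensus of published
# order/disorder propensity rankings (aromatic and branched hydrophobics are
# strong order promoters, Pro/Glu/Lys/Ser strong disorder promoters).  The
# stand-in scorer exists so the pipeline can run without an external disorder
# predictor; it is NOT a re-implementation of any published predictor and its
# absolute values carry no meaning beyond their min-max anchoring.
W	-0.884
F	-0.697
Y	-0.510
I	-0.486
M	-0.397
L	-0.326
V	-0.121
N	0.007
C	0.020
T	0.059
A	0.060
G	0.166
R	0.180
D	0.192
H	0.303
Q	0.318
S	0.341
K	0.586
E	0.736
P	0.987
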