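# SYNTHETIC PLACEHOLDER values for the evolutionary gain/loss propensity of
# each amino acid (normalized difference between substitutions creating and
# removing the residue type; Jordan et al. 2005, Nature 433:633-638). The
# published per-residue fluxes are not bundled here; replace this file with
# the real values (same two-column layout) to reproduce them. The placeholder
# assigns each residue a distinct value on an evenly spaced grid in [-1, 1]
# (alphabetical order) so that the feature is informative of residue identity
# and the pipeline is exercised end to end.
aa	value
A	-1.00
C	-0.90
D	-0.79
E	-0.68
F	-0.58
G	-0.47
H	-0.37
I	-0.26
K	-0.16
L	-0.05
M	0.05
N	0.16
P	0.26
Q	0.37
R	0.47
S	0.58
T	0.68
V	0.79
W	0.90
Y	1.00
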