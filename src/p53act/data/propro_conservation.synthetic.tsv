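# SYNTHETIC PLACEHOLDER values for the conservation propensity of each amino
# acid at protein-protein interfaces (derived from counts of conserved
# interface residues per residue type; Ma et al. 2003, PNAS 100:5772-5777).
# The published propensities are not bundled here; replace this file with the
# real values (same two-column layout) to reproduce them. The placeholder
# assigns each residue a distinct value on an evenly spaced grid in [0, 1]
# (reverse alphabetical order, so it is not collinear with the gain/loss
# placeholder) to keep the feature informative of residue identity.
aa	value
A	1.00
C	0.95
D	0.89
E	0.84
F	0.79
G	0.74
H	0.68
I	0.63
K	0.58
L	0.53
M	0.47
N	0.42
P	0.37
Q	0.32
R	0.26
S	0.21
T	0.16
V	0.11
W	0.05
Y	0.00
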