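# DisProt compositional-bias scale (synthetic stand-in).
# The published scale measures the statistical difference in residue
# composition between disordered regions (DisProt) and ordered proteins;
# the exact table is not redistributable here, so these values are a
# constructed surrogate that preserves the canonical order-promoting
# (W, C, F, I, Y, V, L, N) vs disorder-promoting (A, R, G, Q, S, P, E, K)
# residue ranking of Dunker et al. (2001). Positive = disorder-enriched.
A	0.28
R	0.39
N	-0.14
D	0.09
C	-0.85
Q	0.43
E	0.70
G	0.26
H	-0.08
I	-0.67
L	-0.44
K	0.77
M	-0.05
F	-0.75
P	0.55
S	0.45
T	0.05
W	-0.90
Y	-0.59
V	-0.51
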