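# FoldUnfold scale: expected average number of residue-residue contacts
# in a globular state; low-contact residues favour unfolded regions.
# Transcribed from Garbuzynskiy et al. (2004) / Galzitskaya et al. (2006).
A	23.25
R	22.71
N	20.41
D	20.19
C	27.38
Q	20.67
E	19.38
G	22.03
H	23.55
I	28.34
L	27.62
K	18.57
M	26.95
F	29.55
P	17.43
S	21.28
T	22.90
W	29.00
Y	26.75
V	27.47
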