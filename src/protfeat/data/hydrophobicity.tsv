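# Side-chain hydrophobicity scale at pH 7, relative to glycine = 0, from a
# study of hydrophobicity and alpha-helical propensity in model peptides.
# Source: Monera OD et al. (1995) J Pept Sci 1:319-329 (transcribed).
# columns: aa	value
# sha256: 129fd3fc5292ce9d512075d181a71996de938766515fa82a674deae9fd87a904
A	41
C	49
D	-55
E	-31
F	100
G	0
H	8
I	99
K	-23
L	97
M	74
N	-28
P	-46
Q	-10
R	-14
S	-5
T	13
V	76
W	97
Y	63
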