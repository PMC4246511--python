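# SYNTHETIC stand-in for a cross-strand residue-pairing potential in beta
# sheets. Not transcribed from any publication: built deterministically from
# hydrophobicity/charge complementarity plus a seeded perturbation (see the
# interface table header). Negative = favorable pairing (arbitrary units).
# columns: a	b	value  (unordered pairs, a <= b alphabetically)
# sha256: d3dcd92b3ba3ab24adc8203e793fab7b652d1b8444e1f9823efe745cd8bbad09
A	A	-0.441
A	C	-0.134
A	D	0.366
A	E	0.225
A	F	-0.437
A	G	0.180
A	H	-0.113
A	I	-0.681
A	K	0.037
A	L	-0.419
A	M	-0.369
A	N	-0.002
A	P	0.151
A	Q	-0.153
A	R	-0.077
A	S	-0.334
A	T	0.127
A	V	-0.483
A	W	-0.600
A	Y	-0.307
C	C	-0.365
C	D	0.518
C	E	-0.174
C	F	-0.606
C	G	-0.099
C	H	-0.071
C	I	-0.508
C	K	0.314
C	L	-0.323
C	M	-0.329
C	N	0.250
C	P	0.288
C	Q	-0.101
C	R	-0.048
C	S	0.113
C	T	-0.095
C	V	-0.259
C	W	-0.507
C	Y	-0.212
D	D	0.397
D	E	0.526
D	F	0.630
D	G	0.467
D	H	-0.577
D	I	0.768
D	K	-0.811
D	L	0.570
D	M	0.142
D	N	0.009
D	P	-0.078
D	Q	-0.084
D	R	-0.818
D	S	-0.200
D	T	0.053
D	V	0.667
D	W	0.541
D	Y	0.713
E	E	0.635
E	F	0.333
E	G	-0.187
E	H	-0.362
E	I	0.130
E	K	-0.653
E	L	0.295
E	M	0.004
E	N	-0.090
E	P	-0.288
E	Q	-0.140
E	R	-0.549
E	S	-0.071
E	T	-0.208
E	V	0.219
E	W	0.126
E	Y	0.349
F	F	-1.306
F	G	0.030
F	H	0.041
F	I	-1.084
F	K	0.293
F	L	-1.048
F	M	-0.770
F	N	0.323
F	P	0.583
F	Q	-0.008
F	R	0.140
F	S	0.303
F	T	-0.167
F	V	-1.039
F	W	-1.281
F	Y	-0.638
G	G	-0.215
G	H	0.235
G	I	0.026
G	K	-0.237
G	L	-0.092
G	M	0.063
G	N	-0.056
G	P	0.319
G	Q	0.119
G	R	-0.118
G	S	-0.017
G	T	-0.013
G	V	0.059
G	W	-0.138
G	Y	-0.138
H	H	0.037
H	I	0.103
H	K	0.173
H	L	-0.076
H	M	-0.284
H	N	0.083
H	P	0.167
H	Q	-0.015
H	R	0.513
H	S	-0.107
H	T	-0.111
H	V	-0.201
H	W	0.094
H	Y	-0.292
I	I	-1.291
I	K	0.107
I	L	-1.265
I	M	-1.014
I	N	0.452
I	P	0.660
I	Q	0.387
I	R	0.265
I	S	0.098
I	T	-0.030
I	V	-0.901
I	W	-1.191
I	Y	-0.806
K	K	0.832
K	L	0.096
K	M	-0.002
K	N	-0.027
K	P	0.019
K	Q	0.340
K	R	0.481
K	S	0.271
K	T	0.262
K	V	0.354
K	W	0.013
K	Y	0.103
L	L	-0.965
L	M	-0.656
L	N	0.326
L	P	0.773
L	Q	0.273
L	R	0.250
L	S	0.321
L	T	-0.093
L	V	-0.885
L	W	-1.391
L	Y	-0.821
M	M	-0.601
M	N	0.204
M	P	0.458
M	Q	0.340
M	R	0.226
M	S	-0.061
M	T	-0.210
M	V	-0.621
M	W	-0.993
M	Y	-0.769
N	N	-0.090
N	P	-0.014
N	Q	0.095
N	R	0.102
N	S	0.211
N	T	-0.068
N	V	0.231
N	W	0.190
N	Y	0.128
P	P	-0.324
P	Q	-0.077
P	R	0.188
P	S	0.018
P	T	-0.098
P	V	0.361
P	W	0.592
P	Y	0.214
Q	Q	-0.044
Q	R	-0.083
Q	S	0.094
Q	T	0.140
Q	V	0.213
Q	W	0.020
Q	Y	0.155
R	R	0.424
R	S	0.206
R	T	-0.029
R	V	-0.092
R	W	-0.156
R	Y	0.005
S	S	-0.159
S	T	0.225
S	V	0.184
S	W	0.075
S	Y	0.030
T	T	0.077
T	V	-0.142
T	W	-0.226
T	Y	-0.123
V	V	-0.613
V	W	-0.955
V	Y	-0.643
W	W	-0.838
W	Y	-0.711
Y	Y	-0.253
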