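# SYNTHETIC stand-in for a residue-pair contact potential at protein-protein
# interfaces. Not transcribed from any publication: built deterministically
# from hydrophobicity complementarity and charge interactions plus a seeded
# perturbation, so it has the structure of a knowledge-based potential
# (symmetric, hydrophobic pairs favorable, like charges unfavorable) without
# claiming published digits. Negative = favorable contact (arbitrary units).
# columns: a	b	value  (unordered pairs, a <= b alphabetically)
# sha256: 486bdb4724f88c7052b020b543f1246cf60781dded08f98a104cfbe4ffa1278f
A	A	-0.547
A	C	-0.327
A	D	0.489
A	E	0.299
A	F	-0.852
A	G	-0.259
A	H	0.050
A	I	-1.006
A	K	0.407
A	L	-0.705
A	M	-0.369
A	N	0.392
A	P	0.682
A	Q	0.022
A	R	0.111
A	S	0.192
A	T	0.136
A	V	-0.709
A	W	-0.833
A	Y	-0.494
C	C	-0.646
C	D	0.532
C	E	-0.232
C	F	-1.310
C	G	0.035
C	H	0.300
C	I	-0.652
C	K	0.363
C	L	-0.738
C	M	-0.637
C	N	0.277
C	P	0.361
C	Q	0.094
C	R	0.293
C	S	-0.204
C	T	-0.012
C	V	-0.906
C	W	-0.999
C	Y	-0.582
D	D	0.797
D	E	1.483
D	F	0.998
D	G	-0.397
D	H	-0.569
D	I	0.765
D	K	-1.462
D	L	1.028
D	M	0.838
D	N	-0.358
D	P	-0.647
D	Q	-0.145
D	R	-1.638
D	S	-0.240
D	T	0.135
D	V	0.820
D	W	1.190
D	Y	0.624
E	E	1.303
E	F	0.826
E	G	-0.060
E	H	-0.562
E	I	0.628
E	K	-1.459
E	L	0.591
E	M	0.384
E	N	-0.259
E	P	-0.158
E	Q	-0.088
E	R	-1.537
E	S	-0.187
E	T	0.115
E	V	0.377
E	W	0.483
E	Y	0.428
F	F	-2.313
F	G	0.050
F	H	-0.136
F	I	-1.975
F	K	0.611
F	L	-1.994
F	M	-1.509
F	N	0.449
F	P	0.890
F	Q	0.229
F	R	0.253
F	S	0.333
F	T	-0.072
F	V	-1.494
F	W	-1.861
F	Y	-1.477
G	G	-0.064
G	H	0.227
G	I	-0.089
G	K	0.107
G	L	-0.010
G	M	0.162
G	N	-0.099
G	P	0.099
G	Q	-0.154
G	R	-0.113
G	S	0.032
G	T	-0.056
G	V	0.250
G	W	0.233
G	Y	0.077
H	H	0.405
H	I	-0.426
H	K	0.813
H	L	0.055
H	M	-0.097
H	N	-0.050
H	P	0.057
H	Q	0.069
H	R	0.763
H	S	-0.031
H	T	0.096
H	V	-0.429
H	W	-0.137
H	Y	0.060
I	I	-2.287
I	K	0.442
I	L	-1.857
I	M	-1.578
I	N	0.624
I	P	0.935
I	Q	0.234
I	R	0.299
I	S	0.161
I	T	-0.386
I	V	-1.403
I	W	-1.622
I	Y	-1.344
K	K	1.268
K	L	0.343
K	M	0.230
K	N	-0.053
K	P	-0.427
K	Q	-0.094
K	R	1.366
K	S	-0.003
K	T	0.310
K	V	0.137
K	W	0.313
K	Y	0.451
L	L	-1.687
L	M	-1.589
L	N	0.475
L	P	1.043
L	Q	0.159
L	R	0.199
L	S	0.131
L	T	-0.195
L	V	-1.477
L	W	-1.955
L	Y	-1.199
M	M	-1.021
M	N	0.400
M	P	0.768
M	Q	0.398
M	R	0.328
M	S	-0.141
M	T	-0.424
M	V	-1.204
M	W	-1.438
M	Y	-0.974
N	N	-0.272
N	P	-0.385
N	Q	-0.295
N	R	-0.096
N	S	0.090
N	T	0.014
N	V	0.342
N	W	0.663
N	Y	0.232
P	P	-0.272
P	Q	-0.176
P	R	-0.200
P	S	-0.231
P	T	-0.063
P	V	0.626
P	W	0.932
P	Y	0.549
Q	Q	0.195
Q	R	0.061
Q	S	-0.124
Q	T	-0.204
Q	V	0.416
Q	W	0.303
Q	Y	0.107
R	R	1.740
R	S	-0.059
R	T	0.154
R	V	0.021
R	W	-0.087
R	Y	0.352
S	S	0.124
S	T	0.056
S	V	-0.190
S	W	0.330
S	Y	0.078
T	T	-0.273
T	V	-0.239
T	W	-0.263
T	Y	-0.120
V	V	-1.009
V	W	-1.665
V	Y	-0.870
W	W	-1.860
W	Y	-1.177
Y	Y	-0.567
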