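name	parent	motif
root	-	-
L2a	root	146 152 2416
M	root	489 10400
M5	M	1888
C	M	3552
C4	C	2232
N	root	73 263 1438
N1	N	199
I	N1	250
N2	N	4917
W	N2	1243
N3	N	4856
X	N	6371
X2	X	1719
R	N	12705
R0	R	11719
HV	R0	14766
H	HV	2706 7028
H1	H	3010
H1e1a5	H1	5460
H2	H	1438!
H13	H	4745
H13a	H13	9007
H13a2	H13a	4218
H13a2a1	H13a2	8598
HV2	HV	152 16217
V	HV	4580
R2'JT	R	4216
R2	R2'JT	5426 13734
R2a	R2	2755
R2b	R2	6248
JT	R2'JT	11251
J	JT	295 10398
J1b	J	8269
T	JT	709 15607
R5	R	8594
U	R	11467 12308
U1	U	285
U2	U	5390
U2c	U2	1262
U3	U	150
U5	U	3197
U7	U	8137
K	U	1811
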