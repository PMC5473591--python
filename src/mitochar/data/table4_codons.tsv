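codon	aa	count	rscu
UUU	F	314	1.76
UUC	F	42	0.24
UUA	L	408	4.2
UUG	L	35	0.36
CUU	L	70	0.72
CUC	L	9	0.09
CUA	L	55	0.57
CUG	L	6	0.06
AUU	I	325	1.83
AUC	I	31	0.17
AUA	M	209	1.81
AUG	M	22	0.19
GUU	V	92	1.69
GUC	V	7	0.13
GUA	V	99	1.82
GUG	V	20	0.37
UCU	S	106	2.41
UCC	S	14	0.32
UCA	S	102	2.32
UCG	S	3	0.07
CCU	P	77	2.15
CCC	P	14	0.39
CCA	P	50	1.4
CCG	P	2	0.06
ACU	T	88	2.11
ACC	T	10	0.24
ACA	T	67	1.6
ACG	T	2	0.05
GCU	A	109	2.26
GCC	A	19	0.39
GCA	A	60	1.24
GCG	A	5	0.1
UAU	Y	132	1.69
UAC	Y	24	0.31
UAA	*	11	1.83
UAG	*	1	0.17
CAU	H	59	1.55
CAC	H	17	0.45
CAA	Q	68	1.81
CAG	Q	7	0.19
AAU	N	140	1.74
AAC	N	21	0.26
AAA	K	86	1.74
AAG	K	13	0.26
GAU	D	63	1.77
GAC	D	8	0.23
GAA	E	70	1.82
GAG	E	7	0.18
UGU	C	32	1.83
UGC	C	3	0.17
UGA	W	98	1.9
UGG	W	5	0.1
CGU	R	19	1.41
CGC	R	0	0
CGA	R	30	2.22
CGG	R	5	0.37
AGU	S	40	0.91
AGC	S	1	0.02
AGA	S	74	1.68
AGG	S	12	0.27
GGU	G	82	1.48
GGC	G	6	0.11
GGA	G	119	2.15
GGG	G	14	0.25
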