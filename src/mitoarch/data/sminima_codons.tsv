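# Published codon counts and relative synonymous codon usage (RSCU, 2 dp)
# for the 12 protein-coding genes of the Siliqua minima mitogenome, under
# the invertebrate mitochondrial code (UGA=Trp, AGA/AGG=Ser, AUA=Met;
# Leu is a 6-codon family, Ser an 8-codon family; stops are their own family).
codon	count	rscu
UUU	531	1.68
UUC	102	0.32
UUA	270	2.46
UUG	192	1.75
CUU	99	0.90
CUC	18	0.16
CUA	47	0.43
CUG	32	0.29
AUU	232	1.72
AUC	37	0.28
AUA	109	1.12
AUG	85	0.88
GUU	226	2.05
GUC	34	0.31
GUA	101	0.92
GUG	79	0.72
UCU	121	1.64
UCC	38	0.52
UCA	45	0.61
UCG	26	0.35
CCU	78	2.40
CCC	25	0.77
CCA	16	0.49
CCG	11	0.34
ACU	96	2.37
ACC	23	0.57
ACA	28	0.69
ACG	15	0.37
GCU	107	2.55
GCC	11	0.26
GCA	24	0.57
GCG	26	0.62
UAU	204	1.57
UAC	56	0.43
UAA	140	1.11
UAG	113	0.89
CAU	70	1.63
CAC	16	0.37
CAA	35	1.00
CAG	35	1.00
AAU	201	1.70
AAC	36	0.30
AAA	157	1.17
AAG	112	0.83
GAU	108	1.83
GAC	10	0.17
GAA	93	1.02
GAG	89	0.98
UGU	150	1.53
UGC	46	0.47
UGA	86	0.80
UGG	128	1.20
CGU	40	1.84
CGC	4	0.18
CGA	22	1.01
CGG	21	0.97
AGU	110	1.49
AGC	38	0.52
AGA	100	1.36
AGG	111	1.51
GGU	181	1.54
GGC	59	0.50
GGA	96	0.82
GGG	133	1.13
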