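amino_acid	codon	homo_sapiens	rattus_norvegicus	bos_taurus	mus_musculus	pongo_abelii	average
F	TTT	1.36	0.67	1.0	1.2	1.25	1.32
F	TTC	0.64	1.33	1.0	0.8	0.75	0.68
L	TTA	0.83	0.32	0.53	0.65	0.93	0.80
L	TTG	1.49	0.9	0.86	1.11	1.55	1.44
L	CTT	0.56	0.45	0.46	0.37	0.52	0.55
L	CTC	0.59	1.48	1.52	1.29	0.41	0.65
L	CTA	0.70	0.9	0.46	0.74	0.62	0.70
L	CTG	1.84	1.94	2.18	1.85	1.97	1.86
I	ATT	1.03	1.14	0.79	1.18	0.92	1.02
I	ATC	1.32	1.38	1.74	1.26	1.31	1.33
I	ATA	0.65	0.49	0.47	0.55	0.77	0.64
V	GTT	0.77	0.14	0.62	0.31	0.98	0.74
V	GTC	0.73	0.81	0.97	0.63	0.73	0.74
V	GTA	0.65	0.61	0.55	0.55	0.73	0.64
V	GTG	1.86	2.44	1.86	2.51	1.55	1.88
S	TCT	1.18	1.72	0.83	1.62	1.39	1.21
S	TCC	1.08	1.1	1.66	0.85	1.04	1.09
S	TCA	1.39	0.99	1.07	0.92	1.39	1.36
S	TCG	0.27	0.52	0.53	0.64	0.17	0.29
S	AGT	1.19	0.78	0.53	0.99	1.22	1.16
S	AGC	0.87	0.89	1.37	0.99	0.78	0.89
P	CCT	0.80	1.01	0.71	1.11	0.85	0.81
P	CCC	1.05	1.25	1.15	0.94	0.97	1.05
P	CCA	1.49	1.31	0.93	1.53	1.7	1.47
P	CCG	0.67	0.42	1.21	0.43	0.48	0.66
T	ACT	0.89	0.65	0.88	0.77	0.96	0.88
T	ACC	1.58	1.45	1.76	1.28	1.55	1.57
T	ACA	0.71	1.05	0.78	1.08	0.85	0.74
T	ACG	0.83	0.85	0.59	0.87	0.64	0.82
A	GCT	1.03	0.97	0.78	1.01	0.87	1.02
A	GCC	1.31	1.56	1.7	1.35	1.31	1.33
A	GCA	1.10	1.06	0.74	1.13	1.31	1.09
A	GCG	0.56	0.41	0.78	0.51	0.51	0.56
Y	TAT	0.94	0.5	0.88	0.4	0.9	0.91
Y	TAC	1.06	1.5	1.12	1.6	1.1	1.09
H	CAT	0.87	0.84	0.89	0.89	0.92	0.87
H	CAC	1.13	1.16	1.11	1.11	1.08	1.13
Q	CAA	0.58	0.4	0.2	0.31	0.58	0.55
Q	CAG	1.42	1.6	1.8	1.69	1.42	1.45
N	AAT	0.66	0.73	0.59	0.59	0.67	0.66
N	AAC	1.34	1.27	1.41	1.41	1.33	1.34
K	AAA	1.14	0.92	1.07	0.97	1.13	1.13
K	AAG	0.86	1.08	0.93	1.03	0.87	0.88
D	GAT	0.98	0.92	0.68	0.96	0.98	0.97
D	GAC	1.02	1.08	1.32	1.04	1.02	1.03
E	GAA	0.90	0.7	0.7	0.77	0.93	0.89
E	GAG	1.10	1.3	1.3	1.23	1.07	1.11
C	TGT	1.25	0.92	1.0	1.0	1.25	1.22
C	TGC	0.75	1.08	1.0	1.0	0.75	0.78
R	CGT	0.68	0.35	0.69	0.12	0.71	0.66
R	CGC	1.03	1.04	1.15	1.32	1.0	1.04
R	CGA	1.13	0.81	1.04	0.72	1.29	1.11
R	CGG	1.10	0.92	0.81	1.32	1.0	1.09
R	AGA	1.06	1.15	1.27	1.2	1.14	1.07
R	AGG	0.99	1.73	1.04	1.32	0.86	1.02
G	GGT	0.34	0.43	0.47	0.53	0.34	0.35
G	GGC	0.89	1.07	1.29	0.98	0.94	0.91
G	GGA	1.36	1.5	0.95	1.36	1.36	1.35
G	GGG	1.41	1.0	1.29	1.13	1.36	1.39
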