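amino_acid	preferred_codon	isotypes	total
Ala (A)	GCC	AGC (31), GGC (0), CGC (3), TGC (7)	41
Gly (G)	GGA	ACC (0), GCC (11), CCC (5), TCC (9)	25
Pro (P)	CCA	AGG (8), GGG (0), CGG (3), TGG (6)	17
Thr (T)	ACC	AGT (7), GGT (0), CGT (4), TGT (5)	16
Val (V)	GTG	AAC (6), GAC (0), CAC (6), TAC (3)	15
Ser (S)	TCT	AGA (9), GGA (0), CGA (3), TGA (4), ACT (0), GCT (11)	27
Arg (R)	AGG	ACG (6), GCG (0), CCG (3), TCG (5), CCT (7), TCT (6)	27
Leu (L)	CTG	AAG (6), GAG (0), CAG (10), TAG (3), CAA (3), TAA (2)	24
Phe (F)	TTC	AAA (0), GAA (8)	8
Asn (N)	AAC	ATT (0), GTT (13)	13
Lys (K)	AAG	CTT (11), TTT (6)	17
Asp (D)	GAC	ATC (0), GTC (15)	15
Glu (E)	GAG	CTC (9), TTC (10)	19
His (H)	CAC	ATG (0), GTG (10)	10
Gln (Q)	CAG	CTG (10), TTG (5)	15
Ile (I)	ATC	AAT (8), GAT (0), TAT (3)	11
Tyr (Y)	TAC	ATA (0), GTA (3)	3
Cys (C)	TGC	ACA (0), GCA (40)	40
Trp (W)	TGG	CCA (7)	7
Met (M)	ATG	CAT (8/5)	13
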