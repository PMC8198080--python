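amino_acid	preferred_codon	isotypes	total
Ala (A)	GCC	AGC (13), GGC (0), CGC (9), TGC (11)	33
Gly (G)	GGA	ACC (0), GCC (13), CCC (6), TCC (7)	26
Pro (P)	CCA	AGG (6), GGG (0), CGG (3), TGG (7)	16
Thr (T)	ACC	AGT (9), GGT (0), CGT (4), TGT (4)	17
Val (V)	GTG	AAC (7), GAC (0), CAC (10), TAC (3)	20
Ser (S)	TCT	AGA (8), GGA (0), CGA (3), TGA (3), ACT (0), GCT (7)	21
Arg (R)	CGC/CGG/AGG	ACG (6), GCG (0), CCG (3), TCG (5), CCT (5), TCT (5)	24
Leu (L)	CTG	AAG (5), GAG (0), CAG (10), TAG (3), CAA (4), TAA (4)	26
Phe (F)	TTT	AAA (0), GAA (7)	7
Asn (N)	AAC	ATT (0), GTT (13)	13
Lys (K)	AAG	CTT (19), TTT (13)	32
Asp (D)	GAC	ATC (0), GTC (16)	16
Glu (E)	GAG	CTC (11), TTC (8)	19
His (H)	CAC	ATG (0), GTG (10)	10
Gln (Q)	CAG	CTG (10), TTG (5)	15
Ile (I)	ATC	AAT (11), GAT (0), TAT (4)	15
Tyr (Y)	TAC	ATA (0), GTA (10)	10
Cys (C)	TGC	ACA (0), GCA (54)	54
Trp (W)	TGG	CCA (8)	8
Met (M)	ATG	CAT (9/8)	13
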