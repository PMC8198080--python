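amino_acid	preferred_codon	isotypes	total
Ala (A)	GCC	AGC (22), GGC (0), CGC (4), TGC (8)	34
Gly (G)	GGG	ACC (0), GCC (14), CCC (5), TCC (9)	28
Pro (P)	CCA	AGG (9), GGG (0), CGG (4), TGG (7)	20
Thr (T)	ACC	AGT (9), GGT (0), CGT (5), TGT (6)	20
Val (V)	GTG	AAC (9), GAC (0), CAC (11), TAC (5)	25
Ser (S)	AGT	AGA (9), GGA (0), CGA (4), TGA (4), ACT (0), GCT (8)	25
Arg (R)	CGA	ACG (7), GCG (0), CCG (4), TCG (6), CCT (5), TCT (6)	28
Leu (L)	CTG	AAG (9), GAG (0), CAG (9), TAG (3), CAA (6), TAA (4)	31
Phe (F)	TTT	AAA (0), GAA (10)	10
Asn (N)	AAC	ATT (0), GTT (20)	20
Lys (K)	AAA	CTT (15), TTT (12)	27
Asp (D)	GAC	ATC (0), GTC (13)	13
Glu (E)	GAG	CTC (8), TTC (7)	15
His (H)	CAC	ATG (0), GTG (10)	10
Gln (Q)	CAG	CTG (13), TTG (6)	19
Ile (I)	ATC	AAT (14), GAT (3), TAT (5)	22
Tyr (Y)	TAC	ATA (0), GTA (13)	13
Cys (C)	TGT	ACA (0), GCA (29)	29
Trp (W)	TGG	CCA (7)	7
Met (M)	ATG	CAT (9/10)	19
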