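amino_acid	preferred_codon	isotypes	total
Ala (A)	GCC/GCA	AGC (21), GGC (0), CGC (4), TGC (9)	34
Gly (G)	GGA/GGG	ACC (0), GCC (8), CCC (7), TCC (6)	21
Pro (P)	CCA	AGG (8), GGG (0), CGG (4), TGG (7)	19
Thr (T)	ACC	AGT (10), GGT (0), CGT (5), TGT (6)	21
Val (V)	GTG	AAC (10), GAC (0), CAC (11), TAC (6)	27
Ser (S)	TCA/TCT	AGA (9), GGA (0), CGA (4), TGA (4), ACT (0), GCT (8)	25
Arg (R)	CGA	ACG (7), GCG (0), CCG (4), TCG (6), CCT (5), TCT (6)	28
Leu (L)	CTG	AAG (8), GAG (0), CAG (6), TAG (3), CAA (5), TAA (5)	27
Phe (F)	TTT	AAA (0), GAA (8)	8
Asn (N)	AAC	ATT (0), GTT (22)	22
Lys (K)	AAA	CTT (14), TTT (14)	28
Asp (D)	GAC	ATC (0), GTC (9)	9
Glu (E)	GAG	CTC (5), TTC (14)	19
His (H)	CAC	ATG (0), GTG (12)	12
Gln (Q)	CAG	CTG (11), TTG (6)	17
Ile (I)	ATC	AAT (13), GAT (3), TAT (6)	22
Tyr (Y)	TAC	ATA (0), GTA (12)	12
Cys (C)	TGT	ACA (0), GCA (27)	27
Trp (W)	TGG	CCA (7)	7
Met (M)	ATG	CAT (8/10)	18
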