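amino_acid	preferred_codon	isotypes	total
Ala (A)	GCC	AGC (28), GGC (0), CGC (8), TGC (14)	50
Gly (G)	GGC/GGG	ACC (0), GCC (13), CCC (14), TCC (7)	34
Pro (P)	CCG	AGG (12), GGG (0), CGG (4), TGG (8)	24
Thr (T)	ACC	AGT (12), GGT (0), CGT (4), TGT (8)	24
Val (V)	GTG	AAC (17), GAC (0), CAC (20), TAC (9)	46
Ser (S)	TCC	AGA (12), GGA (2), CGA (5), TGA (4), ACT (0), GCT (17)	40
Arg (R)	CGA	ACG (9), GCG (0), CCG (5), TCG (9), CCT (8), TCT (6)	37
Leu (L)	CTG	AAG (9), GAG (0), CAG (5), TAG (4), CAA (6), TAA (6)	30
Phe (F)	TTT/TTC	AAA (0), GAA (22)	22
Asn (N)	AAC	ATT (0), GTT (28)	28
Lys (K)	AAA	CTT (22), TTT (28)	50
Asp (D)	GAC	ATC (0), GTC (19)	19
Glu (E)	GAG	CTC (7), TTC (34)	41
His (H)	CAC	ATG (0), GTG (15)	15
Gln (Q)	CAG	CTG (22), TTG (7)	29
Ile (I)	ATC	AAT (17), GAT (0), TAT (5)	22
Tyr (Y)	TAC	ATA (0), GTA (16)	16
Cys (C)	TGT/TGC	ACA (0), GCA (27)	27
Trp (W)	TGG	CCA (8)	8
Met (M)	ATG	CAT (16/14)	30
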