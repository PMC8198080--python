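dinucleotide	observed	odds_ratio
AA	0.0883375	1.4133997
AC	0.0669078	1.0705248
AG	0.0948584	1.5177349
AT	0.0504045	0.8064717
CA	0.0842667	1.348268
CC	0.0584552	0.9352831
CG	0.0382312	0.6116988
CT	0.053101	0.8496163
GA	0.0952992	1.5247874
GC	0.0635631	1.0170089
GG	0.0701099	1.121759
GT	0.0415111	0.6641776
TA	0.0326048	0.521676
TC	0.0451281	0.7220494
TG	0.0672838	1.0765401
TT	0.0499378	0.7990044
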