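residue	total_nmol_per_mg	free_nmol_per_mg
Asp	17.02	ND
Thr	8.10	ND
Ser	6.40	ND
Glu	18.71	0.038
Gly	13.42	0.29
Ala	22.20	ND
Cys	ND	ND
Val	14.55	ND
Met	ND	ND
Ile	11.03	0.21
Leu	15.00	0.69
Tyr	6.21	0.29
Phe	2.97	0.40
His	0.26	ND
Lys	10.06	0.45
Arg	8.80	0.60
Pro	4.91	ND
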