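no	sequence	activity
1	WY	7.67
2	WYS	4.45
3	WYSL	4.52
4	WNIP	15.47
5	GWNI	13.9
6	YVEEL	0.799
7	MHIRL	0.306
8	SALAM	2.66
9	WYSLA	4.59
10	AGWNI	8.55
11	LGFEY	9.79
12	GWNIP	6.19
13	WYSLAM	7
14	AGWNIP	7.64
15	LGFEYY	7.25
16	VIPMGL	2.89
17	AGWNIPIGT	5.25
18	LSKAQSDFG	-1.4
19	YAEERYPIL	3.8
20	LVEKGDVAFI	-0.07
21	WYSLAMAASDI	2.621
22	IEWEGIESGSVEQA	0.73
23	AIEWEGIESGSVEQA	0.95
24	IAAEVYEHTEGSTTSY	2.39
25	PIAAEVYEHTEGSTTSY	1.68
26	IANNEADAISLDGGQVFEAG	0.43
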