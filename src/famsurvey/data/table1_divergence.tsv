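pair	gene_a	gene_b	ka	ks	omega_printed	time_printed_mya
1	Glyma.02G140000	Glyma.07G205400	0.1883	0.3374	0.56	27.66
2	Glyma.03G226300	Glyma.19G223300	0.0172	0.1095	0.16	8.98
3	Glyma.04G014700	Glyma.06G014700	0.0204	0.2035	0.10	16.68
4	Glyma.04G014800	Glyma.06G014800	0.0108	0.1554	0.07	12.74
5	Glyma.04G027600	Glyma.06G027700	0.0241	0.1339	0.18	10.98
6	Glyma.04G041500	Glyma.06G042600	0.0849	0.2065	0.41	16.93
7	Glyma.04G190700	Glyma.06G174800	0.0266	0.1233	0.22	10.11
8	Glyma.05G096800	Glyma.17G168300	0.0322	0.1257	0.26	10.30
9	Glyma.05G158600	Glyma.08G116300	0.0832	0.1294	0.64	10.61
10	Glyma.06G272600	Glyma.12G130500		0.1961		16.07
11	Glyma.06G278000	Glyma.12G127200		0.1558		12.77
12	Glyma.09G069800	Glyma.15G177800	0.0334	0.2129	0.16	17.45
13	Glyma.10G207100	Glyma.20G183700	0.0271	0.1038	0.26	8.51
14	Glyma.11G113500	Glyma.12G039400	0.0433	0.1597	0.27	13.09
15	Glyma.11G144900	Glyma.12G077100	0.0397	0.1028	0.39	8.43
16	Glyma.12 g208200	Glyma.13 g292900	0.1635	0.2831	0.58	23.20
17	Glyma.13G229100	Glyma.15G082200	0.093	0.1961	0.47	16.07
18	Glyma.14G216300	Glyma.17G254900	0.0315	0.1857	0.17	15.22
19	Glyma.17G239000	Glyma.14G085800	0.0255	0.1713	0.15	14.04
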