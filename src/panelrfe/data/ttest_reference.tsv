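rank	index	name	pre_mean	pre_sd	post_mean	post_sd	p_value
1	32	MAO	0.85	0.21	0.36	0.18	6.26E-60
2	17	PHOS	1.17	0.17	1.39	0.16	2.17E-39
3	13	LDH	186.02	37.99	158.20	28.07	8.56E-18
4	10	ALP	81.64	20.44	74.34	18.46	9.78E-18
5	16	Ca	2.54	0.13	2.44	0.10	1.68E-16
6	26	CK-MB	9.77	4.76	6.20	3.25	3.56E-15
7	2	ALB	52.19	2.49	50.47	2.42	1.54E-14
8	39	K	4.05	0.33	4.35	0.36	1.63E-14
9	37	ADA	11.5	2.23	10.38	2.09	4.28E-10
10	31	LP(a)	14.15	10.66	11.63	9.11	1.03E-09
11	19	CHOL	4.12	0.64	3.90	0.69	1.11E-09
12	38	Na	144.50	2.74	142.86	2.47	3.51E-09
13	28	APOC2	2.56	1.22	2.87	1.42	2.13E-06
14	22	UIBC	32.21	9.89	36.50	10.84	3.41E-06
15	15	LDL	2.03	0.51	1.91	0.53	8.71E-06
16	34	FRUC	169.57	29.52	181.18	23	9.90E-06
17	6	GLU	3.62	0.46	4.26	1.97	4.90E-05
18	36	TBA	169.57	29.52	181.18	23	8.03E-05
19	41	TIBC	54.99	8.68	56.99	7.56	0.000485
20	1	TP	79.82	5.08	78.02	5	0.000566
21	25	APOB	0.85	0.2	0.82	0.22	0.000977
22	23	Fe	22.79	7.02	20.49	6.94	0.001989
23	4	AST	22.38	5.07	21.14	4.97	0.004223
24	33	PLIP	2.43	0.34	2.36	0.36	0.006711
25	12	CK	171.81	117.62	142.78	100.49	0.009752
26	27	APOA2	27.56	4.34	28.60	4.38	0.021823
27	3	ALT	18.45	8.68	19.98	10.68	0.023629
28	8	Cr	79.44	9.34	78.40	8.23	0.035143
29	29	APOC3	6.94	2.07	7.47	3.45	0.041523
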