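rank	index	name	count	count_pct	mean_accuracy_pct
1	32	MAO	300	100.0	87.37
2	17	PHOS	286	95.33	90.29
3	26	CK-MB	240	80.0	93.7
4	16	Ca	236	78.67	93.44
5	13	LDH	233	77.67	94.12
6	34	FRUC	226	75.33	94.94
7	39	K	210	70.0	95.28
8	38	Na	203	67.67	95.49
9	2	ALB	184	61.33	95.74
10	6	GLU	168	56.0	90.5
11	36	TBA	162	54.0	90.64
12	5	TB	150	50.0	90.56
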