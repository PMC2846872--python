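index,name,pre_mean,pre_sd,post_mean,post_sd,provenance,suspect
1,TP,79.82,5.08,78.02,5,table4,no
2,ALB,52.19,2.49,50.47,2.42,table5,no
3,ALT,18.45,8.68,19.98,10.68,table4,no
4,AST,22.38,5.07,21.14,4.97,table4,no
5,TB,12.0,4.0,12.0,4.0,null_default,no
6,GLU,3.62,0.46,4.26,1.97,table4,no
7,UN,5.2,1.2,5.2,1.2,null_default,no
8,Cr,79.44,9.34,78.40,8.23,table4,no
9,UA,330,60,330,60,null_default,no
10,ALP,81.64,20.44,74.34,18.46,table4,no
11,GGT,25,12,25,12,null_default,no
12,CK,171.81,117.62,142.78,100.49,table4,no
13,LDH,186.02,37.99,158.20,28,table5,no
14,HDL,1.30,0.28,1.30,0.28,null_default,no
15,LDL,2.03,0.51,1.91,0.53,table4,no
16,Ca,2.54,0.13,2.44,0.10,table5,no
17,PHOS,1.17,0.17,1.39,0.16,table5,no
18,Mg,0.88,0.07,0.88,0.07,null_default,no
19,CHOL,4.12,0.64,3.90,0.69,table4,no
20,TG,1.20,0.55,1.20,0.55,null_default,no
21,TCO2,26.0,2.5,26.0,2.5,null_default,no
22,UIBC,32.21,9.89,36.50,10.84,table4,no
23,Fe,22.79,7.02,20.49,6.94,table4,no
24,APOA1,1.40,0.22,1.40,0.22,null_default,no
25,APOB,0.85,0.2,0.82,0.22,table4,no
26,CK-MB,9.77,4.76,6.20,3.25,table5,no
27,APOA2,27.56,4.34,28.60,4.38,table4,no
28,APOC2,2.56,1.22,2.87,1.42,table4,no
29,APOC3,6.94,2.07,7.47,3.45,table4,no
30,APOE,4.0,1.2,4.0,1.2,null_default,no
31,LP(a),14.15,10.66,11.63,9.11,table4,no
32,MAO,0.85,0.21,0.36,0.18,table5,no
33,PLIP,2.43,0.34,2.36,0.36,table4,no
34,FRUC,169.57,29.52,181.18,23,table5,no
35,DB,3.5,1.3,3.5,1.3,null_default,no
36,TBA,169.57,29.52,181.18,23,table4,yes
37,ADA,11.5,2.23,10.38,2.09,table4,no
38,Na,144.49,2.74,142.86,2.47,table5,no
39,K,4.05,0.33,4.35,0.36,table5,no
40,Cl,104,2.5,104,2.5,null_default,no
41,TIBC,54.99,8.68,56.99,7.56,table4,no
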