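id,X,R1,R2,pKi,test,corrected
1,4-Cl,CH3,CF3,5.4,0,
2,3-Cl,CH3,CF3,5.8,0,
3,"3-Cl,5-Cl",CH3,CF3,6.8,0,
4,"3-Cl,4-Cl",CH3,CF3,6.6,1,
5,"2-Cl,3-Cl",CH3,CF3,6.6,1,
6,"2-Cl,6-Cl",CH3,CF3,5.6,1,
7,"3-Cl,4-Cl,5-Cl",CH3,CF3,8.0,1,
8,"2-Cl,3-Cl,5-Cl",CH3,CF3,7.4,0,
9,"2-Cl,4-Cl,6-Cl",CH3,CF3,5.2,0,
10,"2-Cl,3-Cl,6-Cl",CH3,CF3,7.6,0,
11,"2-Cl,4-Cl,5-Cl",CH3,CF3,7.1,0,
12,H,CH3,CF3,4.0,0,
13,"3-Cl,4-Cl,5-Cl",CH(CH3)2,CF3,6.5,0,
14,"3-Cl,4-Cl,5-Cl",CH2C(CH3)3,CF3,6.2,1,
15,"3-Cl,4-Cl,5-Cl",CH2CF3,CF3,7.2,0,
16,"3-Cl,4-Cl,5-Cl",CH2COCH3,CF3,3.8,0,
17,"3-Cl,4-Cl,5-Cl",CH2CN,CF3,7.4,0,
18,"3-Cl,4-Cl,5-Cl",CH2Ph,CF3,3.9,0,
19,"3-Cl,4-Cl,5-Cl",CH2CH2OCH3,CF3,6.6,0,
20,"3-Cl,4-Cl,5-Cl",CH2CH2CH2CH3,CF3,4.0,0,
21,"3-Cl,4-Cl,5-Cl",H,CF3,5.5,1,
22,"3-Cl,4-Cl,5-Cl",NH2,CF3,8.8,0,
23,"3-Cl,4-Cl,5-Cl",NHCOCH3,CF3,5.3,0,
24,"3-Cl,4-Cl,5-Cl",CH3,CH(CH3)2,6.3,0,
25,"3-Cl,4-Cl,5-Cl",CH3,CF2CF2CF3,7.3,0,
26,"3-Cl,4-Cl,5-Cl",CH3,CH2OCH3,5.1,0,
27,"3-Cl,4-Cl,5-Cl",CH3,Ph,4.0,0,
28,"3-Cl,4-Cl,5-Cl",CH3,CH2SO2CH3,42,0,pKi printed as 42; read as 4.2 (outside stated 3.8-9.3 range)
29,"3-Cl,4-Cl,5-Cl",CH3,CH3,4.6,0,
30,"3-Cl,4-Cl,5-Cl",CH3,C(CH3)3,7.5,0,
31,"3-Cl,4-Cl,5-Cl",CH3,CH2SCH3,4.6,0,
32,"3-Cl,4-Cl,5-Cl",CH3,COOH,4.0,0,
33,"3-Cl,4-Cl,5-Cl",CH3,CN,6.2,0,
34,"3-Cl,4-Cl,5-Cl",CH3,CH2CH2CF3,6.4,0,
35,"3-Cl,4-Cl,5-Cl",CH3,CH2CH2CH3,6.2,0,
36,"3-Cl,4-Cl,5-Cl",CH3,CF2CF2CF2CF3,5.0,0,
37,"3-Cl,4-Cl,5-Cl",CH3,2-F-phenyl,4.0,0,
38,"3-Cl,4-Cl,5-Cl",CH3,4-F-phenyl,5.0,1,
39,"3-Cl,4-Cl,5-Cl",CH3,Cl,5.6,1,
40,4-Cl,NH2,CF3,6.7,1,
41,"2-Cl,4-Cl",NH2,CF3,7.5,1,
42,"3-Cl,5-Cl",NH2,CF3,7.7,0,
43,"3-Cl,4-Cl",NH2,CF3,7.7,1,
44,"2-Cl,4-Cl,5-Cl",NH2,CF3,7.5,0,
45,"2-Cl,4-Cl,6-Cl",NH2,CF3,7.5,1,
46,"2-Cl,6-Cl",NH2,CF3,7.1,0,
47,3-Cl,NH2,CF3,6.5,0,
48,"2-Cl,3-Cl,4-Cl",NH2,CF3,8.5,0,
49,H,NH2,CF3,5,0,pKi printed as bare 5; read as 5.0
50,"3-Cl,4-I,5-Cl",NH2,CF3,9.3,0,
51,"3-Cl,4-SOCH3,5-Cl",NH2,CF3,7.5,0,
52,"3-Cl,4-SCH3,5-Cl",NH2,CF3,8.7,0,
53,"3-Cl,4-Ph,5-Cl",NH2,CF3,8.9,1,
54,"3-Cl,4-OCH3,5-Cl",NH2,CF3,8.5,0,
55,"3-Cl,4-(2-thienyl),5-Cl",NH2,CF3,9.1,0,
56,"3-Cl,4-N(CH3)2,5-Cl",NH2,CF3,8.8,1,
57,"3-Cl,4-OCH(CH3)2,5-Cl",NH2,CF3,9.0,0,
58,"3-Cl,4-Br,5-Cl",NH2,CF3,9.3,0,
59,"3-Cl,4-CF2CF3,5-Cl",NH2,CF3,8.8,0,
60,"3-F,4-CF3,5-F",NH2,CF3,8.7,1,
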