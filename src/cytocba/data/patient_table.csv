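patient_id,age,sex,subtype,mgfa_class,ck,achr_titer,myositis,myocarditis,outcome,titin_cba,kv14_cba,titin_former,kv14_former
1,34,F,TMG,5,27170,240,+,+,Dead,+,+,+,+
2,62,M,TMG,5,9835,280,+,+,Dead,+,+,+,+
3,69,F,TMG,5,1250,6.5,+,+,Dead,+,+,+,+
4,80,F,TMG,5,3107,344,+,+,Alive,+,-,+,+
5,52,F,TMG,3b,1270,28,+,+,Dead,+,+,+,+
6,66,F,LOMG,3a,16489,<0.2,+,+,Alive,-,+,-,+
7,48,F,EOMG,5,3482,92,+,-,Alive,+,-,+,+
8,50,F,TMG,5,99,800,+,-,Alive,+,+,+,+
9,62,F,LOMG,5,3193,590,+,-,Alive,+,-,+,-
10,63,F,TMG,5,3432,19,+,-,Alive,+,+,+,+
11,73,F,TMG,5,4424,70,+,-,Alive,+,-,+,+
12,80,M,LOMG,5,2300,99,+,-,Alive,+,-,+,ND
13,68,F,LOMG,4b,362,150,+,-,Alive,+,-,+,+
14,49,F,TMG,3b,465,32,+,-,Alive,+,-,+,-
15,58,F,TMG,3b,11117,87,+,-,Alive,+,+,+,+
16,63,F,LOMG,3b,965,112,+,-,Alive,+,+,+,+
17,59,M,TMG,3a,10226,12,+,-,Alive,+,+,+,+
18,45,F,TMG,5,67,390,-,+,Alive,+,-,-,+
19,46,M,TMG,5,267,86,-,+,Dead,+,-,+,ND
20,52,F,TMG,5,810,230,-,+,Dead,+,+,+,+
21,53,F,TMG,5,397,130,-,+,Alive,+,-,-,+
22,59,M,TMG,5,102,23,-,+,Alive,+,-,-,-
23,76,M,TMG,5,745,2.5,-,+,Dead,+,-,-,ND
24,82,F,LOMG,5,401,48,-,+,Alive,-,+,-,+
25,51,M,TMG,4b,66,57,-,+,Alive,+,+,-,+
26,74,M,LOMG,4a,120,72,-,+,Alive,+,-,-,ND
27,59,F,TMG,3b,681,180,-,+,Dead,+,+,+,+
28,60,F,TMG,3b,69,200,-,+,Alive,+,-,+,ND
29,63,F,TMG,3b,43,370,-,+,Alive,+,+,-,+
30,57,F,LOMG,3a,1013,15,-,+,Alive,+,-,+,ND
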