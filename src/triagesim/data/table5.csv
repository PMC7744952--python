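patient,chest_pain,short_breath,palpitation,at_rest,spo2,bp_high_printed,bp_low_printed
1,false,false,false,false,97,12,23
2,true,false,false,false,97,12,23
3,false,true,false,false,97,12,23
4,true,true,false,false,97,12,23
5,false,false,true,false,97,12,23
6,true,false,true,false,97,12,23
7,false,true,true,false,97,12,23
8,true,true,true,false,97,12,23
9,false,false,false,true,97,12,23
10,true,false,false,true,97,12,23
11,false,true,false,true,97,12,23
12,true,true,false,true,97,12,23
13,false,false,true,true,97,12,23
14,true,false,true,true,97,12,23
15,false,true,true,true,97,12,23
16,true,true,true,true,97,12,23
17,false,false,false,false,92,12,23
18,true,false,false,false,92,12,23
19,false,true,false,false,92,12,23
20,true,true,false,false,92,12,23
21,false,false,true,false,92,12,23
22,true,false,true,false,92,12,23
23,false,true,true,false,92,12,23
24,true,true,true,false,92,12,23
25,false,false,false,true,92,12,23
26,true,false,false,true,92,12,23
27,false,true,false,true,92,12,23
28,true,true,false,true,92,12,23
29,false,false,true,true,92,12,23
30,true,false,true,true,92,12,23
31,false,true,true,true,92,12,23
32,true,true,true,true,92,12,23
33,false,false,false,false,97,10,15
34,true,false,false,false,97,10,15
35,false,true,false,false,97,10,15
36,true,true,false,false,97,10,15
37,false,false,true,false,97,10,15
38,true,false,true,false,97,10,15
39,false,true,true,false,97,10,15
40,true,true,true,false,97,10,15
41,false,false,false,true,97,10,15
42,true,false,false,true,97,10,15
43,false,true,false,true,97,10,15
44,true,true,false,true,97,10,15
45,false,false,true,true,97,10,15
46,true,false,true,true,97,10,15
47,false,true,true,true,97,10,15
48,true,true,true,true,97,10,15
49,false,false,false,false,92,10,15
50,true,false,false,false,92,10,15
51,false,true,false,false,92,10,15
52,true,true,false,false,92,10,15
53,false,false,true,false,92,10,15
54,true,false,true,false,92,10,15
55,false,true,true,false,92,10,15
56,true,true,true,false,92,10,15
57,false,false,false,true,92,10,15
58,true,false,false,true,92,10,15
59,false,true,false,true,92,10,15
60,true,true,false,true,92,10,15
61,false,false,true,true,92,10,15
62,true,false,true,true,92,10,15
63,false,true,true,true,92,10,15
64,true,true,true,true,92,10,15
65,false,false,false,false,97,8,12
66,true,false,false,false,97,8,12
67,false,true,false,false,97,8,12
68,true,true,false,false,97,8,12
69,false,false,true,false,97,8,12
70,true,false,true,false,97,8,12
71,false,true,true,false,97,8,12
72,true,true,true,false,97,8,12
73,false,false,false,true,97,8,12
74,true,false,false,true,97,8,12
75,false,true,false,true,97,8,12
76,true,true,false,true,97,8,12
77,false,false,true,true,97,8,12
78,true,false,true,true,97,8,12
79,false,true,true,true,97,8,12
80,true,true,true,true,97,8,12
81,false,false,false,false,92,8,12
82,true,false,false,false,92,8,12
83,false,true,false,false,92,8,12
84,true,true,false,false,92,8,12
85,false,false,true,false,92,8,12
86,true,false,true,false,92,8,12
87,false,true,true,false,92,8,12
88,true,true,true,false,92,8,12
89,false,false,false,true,92,8,12
90,true,false,false,true,92,8,12
91,false,true,false,true,92,8,12
92,true,true,false,true,92,8,12
93,false,false,true,true,92,8,12
94,true,false,true,true,92,8,12
95,false,true,true,true,92,8,12
96,true,true,true,true,92,8,12
97,false,false,false,false,80,8,12
98,true,false,false,false,80,8,12
99,false,true,false,false,80,8,12
100,true,true,false,false,80,8,12
101,false,false,true,false,80,8,12
102,true,false,true,false,80,8,12
103,false,true,true,false,80,8,12
104,true,true,true,false,80,8,12
105,false,false,false,true,80,8,12
106,true,false,false,true,80,8,12
107,false,true,false,true,80,8,12
108,true,true,false,true,80,8,12
109,false,false,true,true,80,8,12
110,true,false,true,true,80,8,12
111,false,true,true,true,80,8,12
112,true,true,true,true,80,8,12
113,false,false,false,false,80,10,15
114,true,false,false,false,80,10,15
115,false,true,false,false,80,10,15
116,true,true,false,false,80,10,15
117,false,false,true,false,80,10,15
118,true,false,true,false,80,10,15
119,false,true,true,false,80,10,15
120,true,true,true,false,80,10,15
121,false,false,false,true,80,10,15
122,true,false,false,true,80,10,15
123,false,true,false,true,80,10,15
124,true,true,false,true,80,10,15
125,false,false,true,true,80,10,15
126,true,false,true,true,80,10,15
127,false,true,true,true,80,10,15
128,true,true,true,true,80,10,15
129,false,false,false,false,80,12,23
130,true,false,false,false,80,12,23
131,false,true,false,false,80,12,23
132,true,true,false,false,80,12,23
133,false,false,true,false,80,12,23
134,true,false,true,false,80,12,23
135,false,true,true,false,80,12,23
136,true,true,true,false,80,12,23
137,false,false,false,true,80,12,23
138,true,false,false,true,80,12,23
139,false,true,false,true,80,12,23
140,true,true,false,true,80,12,23
141,false,false,true,true,80,12,23
142,true,false,true,true,80,12,23
143,false,true,true,true,80,12,23
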