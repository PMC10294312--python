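age,probability
20,2e-06
21,2.49146e-06
22,3.10369e-06
23,3.86636e-06
24,4.81645e-06
25,6e-06
26,8.27838e-06
27,1.14219e-05
28,1.57592e-05
29,2.17434e-05
30,3e-05
31,3.73719e-05
32,4.65554e-05
33,5.79955e-05
34,7.22467e-05
35,9e-05
36,9.9681e-05
37,0.000110403
38,0.000122279
39,0.000135432
40,0.00015
41,0.000167443
42,0.000186915
43,0.000208651
44,0.000232915
45,0.00026
46,0.000286173
47,0.000314981
48,0.000346688
49,0.000381587
50,0.00042
51,0.000451055
52,0.000484407
53,0.000520224
54,0.00055869
55,0.0006
56,0.000637115
57,0.000676526
58,0.000718375
59,0.000762813
60,0.00081
61,0.000849876
62,0.000891715
63,0.000935613
64,0.000981673
65,0.00103
66,0.00107066
67,0.00111293
68,0.00115686
69,0.00120253
70,0.00125
71,0.00130663
72,0.00136583
73,0.00142771
74,0.00149239
75,0.00156
76,0.0016587
77,0.00176364
78,0.00187522
79,0.00199386
80,0.00212
81,0.00225709
82,0.00240304
83,0.00255843
84,0.00272386
85,0.0029
86,0.00297592
87,0.00305383
88,0.00313377
89,0.00321581
90,0.0033
91,0.0033
92,0.0033
93,0.0033
94,0.0033
95,0.0033
96,0.0033
97,0.0033
98,0.0033
99,0.0033
100,0.0033
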