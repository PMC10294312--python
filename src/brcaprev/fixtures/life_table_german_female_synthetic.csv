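age,probability
20,0.00016
21,0.000167302
22,0.000174938
23,0.000182922
24,0.00019127
25,0.0002
26,0.000215429
27,0.000232048
28,0.000249949
29,0.000269231
30,0.00029
31,0.000312297
32,0.000336309
33,0.000362167
34,0.000390013
35,0.00042
36,0.000465178
37,0.000515215
38,0.000570635
39,0.000632016
40,0.0007
41,0.000777061
42,0.000862604
43,0.000957565
44,0.00106298
45,0.00118
46,0.00131264
47,0.00146018
48,0.00162432
49,0.0018069
50,0.00201
51,0.00222221
52,0.00245682
53,0.0027162
54,0.00300296
55,0.00332
56,0.00362329
57,0.00395429
58,0.00431552
59,0.00470975
60,0.00514
61,0.00562808
62,0.0061625
63,0.00674768
64,0.00738842
65,0.00809
66,0.0089005
67,0.0097922
68,0.0107732
69,0.0118525
70,0.01304
71,0.0144182
72,0.0159421
73,0.017627
74,0.0194901
75,0.02155
76,0.024183
77,0.0271378
78,0.0304536
79,0.0341745
80,0.03835
81,0.0439499
82,0.0503674
83,0.0577221
84,0.0661507
85,0.07581
86,0.0865738
87,0.0988658
88,0.112903
89,0.128934
90,0.14724
91,0.164531
92,0.183853
93,0.205444
94,0.22957
95,0.25653
96,0.279715
97,0.304995
98,0.332561
99,0.362617
100,0.39539
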