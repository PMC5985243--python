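age,q
0,0.00053476236513487995
1,0.00053827751376108802
2,0.00054214683117852821
3,0.00054640600007751941
4,0.00055109429786245369
5,0.00055625495871627472
6,0.00056193557211754491
7,0.00056818852147695912
8,0.00057507146692834475
9,0.0005826478767142015
10,0.00059098761205131985
11,0.00060016757085199521
12,0.0006102723962152219
13,0.00062139525619481586
14,0.00063363870200299616
15,0.00064711561252430512
16,0.00066195023380225936
17,0.00067827932302670061
18,0.0006962534075010961
19,0.00071603817011430503
20,0.00073781597398967739
21,0.00076178754024569095
22,0.0007881737941874675
23,0.00081721789676922818
24,0.00084918747983685704
25,0.0008843771054911901
26,0.00092311097192153597
27,0.0009657458902616623
28,0.0010126745594347748
29,0.0010643291685989659
30,0.001121185359700859
31,0.0011837665858147749
32,0.001252648904411394
33,0.0013284662484887889
34,0.0014119162226366544
35,0.0015037664756198037
36,0.0016048617059892906
37,0.0017161313625897103
38,0.001838598107661353
39,0.0019733871165684685
40,0.0021217362950528376
41,0.0022850075023475606
42,0.0024646988765205727
43,0.002662458367080075
44,0.0028800985891899058
45,0.0031196131238321882
46,0.0033831943989299932
47,0.0036732532978067571
48,0.0039924406534011274
49,0.0043436707993474407
50,0.0047301473623223289
51,0.0051553914938674821
52,0.0056232727541116996
53,0.0061380428742705629
54,0.0067043726392816026
55,0.0073273921461489908
56,0.0080127347071499017
57,0.0087665846795153858
58,0.0095957295139325952
59,0.010507616322457442
60,0.011510413271222387
61,0.012613076103490361
62,0.013825420092687633
63,0.015158197711263286
64,0.016623182277402952
65,0.018233257805143628
66,0.020002515231131827
67,0.021946355119349902
68,0.02408159684908949
69,0.026426594165926139
70,0.029001356814145219
71,0.031827677764616952
72,0.034929265295962124
73,0.038331878869144735
74,0.042063467345148674
75,0.046154307619504308
76,0.050637141172089478
77,0.055547305340525301
78,0.060922855304289029
79,0.066804671797493567
80,0.07323654843442827
81,0.080265251218001737
82,0.087940541294619798
83,0.096315150312313122
84,0.10544469583272111
85,0.11538752215456928
86,0.12620444965653566
87,0.13795841341474163
88,0.1507139694804146
89,0.16453664494433157
90,0.17949210594772397
91,0.19564511637210746
92,0.21305825938104483
93,0.23179039471708282
94,0.2518948272042606
95,0.27341716690948364
96,0.29639286962204064
97,0.32084445855715393
98,0.3467784453631681
99,0.37418199147431869
100,0.40301938032137946
101,0.43322840729581635
102,0.46471683751391857
103,0.49735913034513229
104,0.53099368213248488
105,0.56542089070022561
106,0.60040239126868733
107,0.63566184515771285
108,0.67088766973874014
109,0.70573806818749962
110,1
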