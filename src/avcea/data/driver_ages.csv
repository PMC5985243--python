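age,weight
16,0.009769539078156312
17,0.009769539078156312
18,0.009769539078156312
19,0.009769539078156312
20,0.017434869739478956
21,0.017434869739478956
22,0.017434869739478956
23,0.017434869739478956
24,0.017434869739478956
25,0.018036072144288578
26,0.018036072144288578
27,0.018036072144288578
28,0.018036072144288578
29,0.018036072144288578
30,0.017635270541082167
31,0.017635270541082167
32,0.017635270541082167
33,0.017635270541082167
34,0.017635270541082167
35,0.017234468937875752
36,0.017234468937875752
37,0.017234468937875752
38,0.017234468937875752
39,0.017234468937875752
40,0.016833667334669341
41,0.016833667334669341
42,0.016833667334669341
43,0.016833667334669341
44,0.016833667334669341
45,0.017034068136272545
46,0.017034068136272545
47,0.017034068136272545
48,0.017034068136272545
49,0.017034068136272545
50,0.017635270541082167
51,0.017635270541082167
52,0.017635270541082167
53,0.017635270541082167
54,0.017635270541082167
55,0.017434869739478956
56,0.017434869739478956
57,0.017434869739478956
58,0.017434869739478956
59,0.017434869739478956
60,0.015831663326653308
61,0.015831663326653308
62,0.015831663326653308
63,0.015831663326653308
64,0.015831663326653308
65,0.013426853707414831
66,0.013426853707414831
67,0.013426853707414831
68,0.013426853707414831
69,0.013426853707414831
70,0.01002004008016032
71,0.01002004008016032
72,0.01002004008016032
73,0.01002004008016032
74,0.01002004008016032
75,0.0066132264529058108
76,0.0066132264529058108
77,0.0066132264529058108
78,0.0066132264529058108
79,0.0066132264529058108
80,0.0042084168336673352
81,0.0042084168336673352
82,0.0042084168336673352
83,0.0042084168336673352
84,0.0042084168336673352
85,0.0023380093520374082
86,0.0023380093520374082
87,0.0023380093520374082
88,0.0023380093520374082
89,0.0023380093520374082
90,0.0023380093520374082
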