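vehicle_age,expire_prob
1,1.5268940583346158e-05
2,0.0002290096306121056
3,0.00099199636103518697
4,0.0026685181606335602
5,0.0056184392910123213
6,0.010193230622319751
7,0.016730767919599085
8,0.025549008168483444
9,0.03693871148032387
10,0.051155440285298663
11,0.06841113561227434
12,0.088865637303068123
13,0.11261857503887479
14,0.13970210334970581
15,0.17007497932048607
16,0.2036184798039396
17,0.2401346199684497
18,0.27934706320324149
19,0.32090500272497985
20,0.36439015001607272
21,0.40932679064130606
22,0.45519467410984915
23,0.50144430487807334
24,0.54751401257302146
25,0.5928480185724474
26,0.63691460021723323
27,0.67922339767039075
28,0.71934092181962983
29,0.7569034085542522
30,0.79162632192105364
31,1
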