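patient,phi,theta
1,1.599,0.422
2,1.208,0.463
3,1.456,0.733
4,2.098,0.733
5,1.401,0.684
6,1.819,0.944
7,1.569,0.757
8,1.562,0.705
9,1.850,0.632
10,0.639,0.644
11,1.696,0.930
12,1.965,0.429
13,1.470,0.981
14,1.744,1.023
15,1.674,1.286
16,1.382,0.937
17,0.557,0.909
18,1.688,0.642
19,1.628,0.724
20,1.560,0.656
21,1.808,0.646
22,2.089,0.471
23,2.293,0.154
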