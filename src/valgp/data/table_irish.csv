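state,n,observed_mean,prior_mean,prior_sd,single_mean,single_sd,combined_mean,combined_sd
11111,0,1,1,0,1,0,1,0
11112,41,0.9122,0.9198,0.0351,0.8929,0.0364,0.8933,0.0318
11121,41,0.9549,0.9070,0.0399,0.9163,0.0430,0.9282,0.0374
11211,41,0.9622,0.9692,0.0388,0.9699,0.0397,0.9682,0.0341
11453,41,0.1598,0.1744,0.0672,0.0054,0.0641,0.1212,0.0602
12111,41,0.9463,0.9059,0.0365,0.9273,0.0363,0.9477,0.0324
12112,41,0.8500,0.8385,0.0384,0.8307,0.0381,0.8485,0.0344
13541,41,0.2024,0.2586,0.0627,0.1626,0.0584,0.1938,0.0525
14335,41,-0.0671,0.0655,0.0685,-0.1419,0.0658,-0.1005,0.0604
15224,41,0.2024,0.2639,0.0633,0.0874,0.0620,0.2358,0.0561
21111,41,0.9585,0.9280,0.0395,0.9456,0.0400,0.9714,0.0353
21514,41,0.2915,0.3510,0.0611,0.2007,0.0610,0.2320,0.0542
22245,41,-0.1171,0.1296,0.0652,-0.1373,0.0657,-0.1212,0.0591
23323,41,0.5805,0.6127,0.0498,0.5452,0.0496,0.5314,0.0431
24151,41,-0.0207,0.0919,0.0674,-0.0557,0.0640,-0.0103,0.0557
25432,41,0.2073,0.2582,0.0598,0.1470,0.0575,0.1558,0.0515
31125,41,0.2354,0.3022,0.0626,0.1050,0.0615,0.1399,0.0571
32533,41,0.3768,0.4407,0.0552,0.3208,0.0541,0.2997,0.0488
33252,76,0.1467,0.1508,0.0570,0.0362,0.0511,0.1151,0.0488
34444,41,-0.3463,-0.0071,0.0708,-0.2874,0.0710,-0.2946,0.0618
35311,41,0.6646,0.5602,0.0524,0.6011,0.0523,0.6139,0.0470
41231,41,0.7085,0.6712,0.0499,0.6639,0.0506,0.6612,0.0447
42354,41,-0.3293,-0.0225,0.0730,-0.3120,0.0717,-0.2924,0.0641
43415,41,0.0134,0.0797,0.0706,-0.0533,0.0644,0.0038,0.0589
44522,41,0.3268,0.3342,0.0597,0.2870,0.0539,0.3057,0.0491
45143,41,-0.1451,0.0978,0.0686,-0.1334,0.0677,-0.1400,0.0597
51342,41,0.1390,0.3050,0.0577,0.1284,0.0581,0.1344,0.0511
52421,41,0.5805,0.4888,0.0556,0.5060,0.0522,0.5390,0.0483
53134,41,0.1598,0.1768,0.0663,0.0184,0.0625,0.1854,0.0590
54213,41,0.2549,0.2913,0.0594,0.2097,0.0559,0.2407,0.0507
55555,123,-0.6053,-0.2506,0.0737,-0.5505,0.0679,-0.5509,0.0638
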