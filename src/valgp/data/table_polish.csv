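state,n,observed_mean,prior_mean,prior_sd,single_mean,single_sd,combined_mean,combined_sd
11111,0,1,1,0,1,0,1,0
11112,39,0.9269,0.9044,0.0326,0.9122,0.0385,0.9218,0.0322
11121,40,0.9137,0.9357,0.0385,0.8981,0.0437,0.9278,0.0362
11211,39,0.9577,0.9715,0.0355,0.9663,0.0425,0.9624,0.0349
11453,40,0.0812,0.1503,0.0574,0.0956,0.0736,0.1196,0.0622
12111,40,0.9062,0.9531,0.0325,0.8969,0.0400,0.9122,0.0325
12112,40,0.8262,0.8643,0.0341,0.8230,0.0420,0.8444,0.0348
13541,40,0.2037,0.2780,0.0523,0.1878,0.0687,0.1796,0.0579
14335,40,0.0075,0.0144,0.0589,-0.0238,0.0751,-0.0025,0.0637
15224,40,0.2513,0.1902,0.0555,0.1937,0.0693,0.2412,0.0591
21111,40,0.9025,0.9744,0.0359,0.9211,0.0433,0.9328,0.0352
21514,40,0.2900,0.3122,0.0546,0.2890,0.0669,0.2711,0.0561
22245,39,-0.0167,-0.0041,0.0588,0.0465,0.0714,0.0417,0.0628
23323,39,0.6308,0.5803,0.0444,0.5757,0.0546,0.5914,0.0467
24151,39,-0.0897,0.0952,0.0573,0.0052,0.0738,-0.0664,0.0631
25432,39,0.1949,0.2439,0.0515,0.1873,0.0655,0.1743,0.0577
31125,40,0.2587,0.2297,0.0550,0.2355,0.0686,0.2414,0.0584
32533,39,0.4359,0.3728,0.0484,0.3873,0.0605,0.3911,0.0523
33252,79,0.1000,0.1716,0.0458,0.0697,0.0625,0.1006,0.0541
34444,39,-0.2167,-0.1415,0.0636,-0.1032,0.0775,-0.1815,0.0677
35311,40,0.5662,0.6542,0.0468,0.5182,0.0574,0.5341,0.0503
41231,40,0.6763,0.6966,0.0453,0.6398,0.0546,0.6628,0.0458
42354,40,-0.1313,-0.1575,0.0642,-0.1201,0.0800,-0.1462,0.0685
43415,40,-0.0387,0.1078,0.0576,-0.0081,0.0773,-0.0126,0.0642
44522,40,0.2913,0.3782,0.0483,0.2706,0.0654,0.2729,0.0547
45143,40,0.0775,-0.0210,0.0606,0.0116,0.0752,0.0529,0.0663
51342,39,0.2256,0.2248,0.0521,0.2386,0.0632,0.1983,0.0564
52421,40,0.4575,0.5871,0.0467,0.4400,0.0609,0.4583,0.0507
53134,40,0.1562,0.1451,0.0560,0.0982,0.0727,0.1230,0.0616
54213,39,0.1987,0.3200,0.0501,0.2236,0.0651,0.2179,0.0557
55555,119,-0.5723,-0.3710,0.0608,-0.3701,0.0808,-0.4750,0.0718
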