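COND,5,200,1987,3850,5650,7450,9238,16000
1,305009,30744,8657,6607,5547,4885,4453,3856
2,238883,27665,7087,5198,4257,3619,3260,2709
3,210094,26599,6599,4776,3891,3278,2939,2404
7,119218,23260,5395,3755,2970,2408,2121,1638
11,83554,21773,4959,3403,2658,2120,1853,1389
17,55698,19764,4589,3118,2417,1902,1651,1204
23,42127,17997,4340,2941,2270,1776,1537,1105
31,31820,16183,4100,2775,2135,1658,1432,1015
43,23303,14031,3840,2604,2000,1543,1332,929
61,16604,11576,3550,2423,1863,1431,1236,851
89,11498,8897,3207,2215,1707,1305,1130,766
127,8066,6634,2845,2005,1555,1188,1033,692
179,5706,4889,2461,1784,1401,1075,939,623
251,4055,3563,2077,1558,1242,961,844,557
349,2939,2630,1734,1349,1097,859,759,503
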