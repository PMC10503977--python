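compound,logP(o/w),SlogP_VSA4,vsurf_IW3,BCUT_SMR_2,pIC50_obs,pIC50_pred,pIC50_loo,split
8b,4.9518,33.4189,2.4626,0.7751,6.5968,6.7780,6.8746,train
9a,4.0580,30.2334,2.8303,0.8189,6.1007,6.2360,6.2645,train
10a,4.0210,30.2334,2.1943,0.8309,6.3269,6.5958,6.6497,train
10b,4.9538,33.4189,0.4323,0.7648,7.7958,7.5893,7.4689,train
10c,4.9928,33.4189,2.0546,0.7876,6.8386,7.0902,7.1913,train
10e,4.1720,30.2334,1.8544,0.8309,7.2518,6.8420,6.7629,train
10f,4.6110,30.2334,2.3715,0.8311,7.1611,6.8939,6.8292,train
10g,3.9750,30.2334,1.8080,0.7969,6.3777,6.4492,6.4735,train
11g,3.7110,30.2334,2.8445,0.8335,6.2048,6.1328,6.1054,train
12b,4.0930,3.1856,1.5152,0.8826,5.5497,5.8354,5.8976,train
15a,4.1648,6.3712,1.8161,0.7838,5.2232,5.0928,5.0162,train
15b,3.8220,3.1856,3.0879,0.9392,5.2831,5.4470,5.5726,train
16a,4.6258,6.3712,1.5711,0.7690,5.4723,5.3691,5.3122,train
16b,4.6648,6.3712,1.2923,0.8091,5.3106,5.8565,5.9500,train
16c,4.6278,6.3712,0.7767,0.8543,6.5482,6.4438,6.4168,train
17a,4.5888,6.3712,1.2236,0.8543,6.2365,6.2213,6.2190,train
18a,4.5908,6.3712,0.2897,0.8543,6.6516,6.6357,6.6276,train
19a,4.1450,3.1856,2.0563,0.8543,5.2306,5.3892,5.4115,train
20a,4.1010,3.1856,2.5898,0.8543,5.5867,5.1253,5.0201,train
20b,4.6910,3.1856,2.3541,0.8718,6.0282,5.7528,5.6333,train
10d,4.9558,33.4189,1.4270,0.8270,6.7014,7.6778,,test
10h,4.0140,30.2334,2.1155,0.7972,5.8551,6.3405,,test
11a,3.7570,30.2334,2.9518,0.8543,6.7399,6.2909,,test
11b,4.6898,33.4189,1.6233,0.8175,7.2441,7.3417,,test
12a,4.4358,6.3712,1.5940,0.7690,5.0762,5.2381,,test
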