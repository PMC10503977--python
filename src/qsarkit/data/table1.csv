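compound,pIC50
8b,6.5969
9a,6.1007
10a,6.3270
10b,7.7959
10c,6.8386
10d,6.7011
10e,7.2518
10f,7.1612
10g,6.3778
10h,5.8551
11a,6.7399
11b,7.2441
11g,6.2048
12a,5.0762
12b,5.5498
15a,5.2233
15b,5.2832
16a,5.4724
16b,5.3107
16c,6.5482
17a,6.2366
18a,6.6517
19a,5.2306
20a,5.5867
20b,6.0283
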