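compound,pIC50,binding_affinity
8b,6.5968,-9.4
9a,6.1007,-9.5
9b,5.6740,-9.5
10a,6.3269,-9.2
10b,7.7958,-9.9
10c,6.8386,-9.6
10d,6.70114,-9.3
10e,7.2518,-9.7
10f,7.1611,-9.6
10g,6.3777,-9.3
10h,5.8551,-9.3
11a,6.7399,-9.4
11b,7.2441,-9.5
11g,6.2048,-9.4
12b,5.5497,-8.5
15a,5.2232,-7.9
15b,5.2831,-8.1
16a,5.4723,-8.5
16b,5.3106,-8.3
16c,6.5482,-9.4
17a,6.2365,-9.1
18a,6.6516,-9.2
19a,5.2306,-8.3
20a,5.5867,-8.7
20b,6.0282,-9.2
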