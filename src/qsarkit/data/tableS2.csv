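compound,MW,LogP,HBA,HBD,TPSA,lipinski,lipinski_violations,ghose,ghose_violations,ghose_violated_conditions,veber,egan,muegge,bioavailability_score
8b,306.28,4.61,5,0,26.30,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
9a,238.28,3.59,2,0,26.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
9b,306.28,4.61,5,0,26.30,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
10a,238.28,3.59,2,0,26.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
10b,306.28,4.61,2,0,26.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
10c,306.28,4.61,5,0,26.30,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
10d,306.28,4.61,5,0,26.30,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
10e,256.27,3.73,3,0,26.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
10f,272.73,4.24,2,0,26.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
10g,268.31,3.59,3,0,35.53,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
10h,268.31,3.59,3,0,35.53,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
11a,224.25,3.28,2,1,37.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
11b,292.25,4.30,5,1,37.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
11g,254.28,3.29,3,1,46.33,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
12b,257.71,3.99,4,1,29.10,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
15a,307.27,4.06,5,2,49.33,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
15b,273.71,3.69,2,2,49.33,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
16a,309.26,4.49,5,1,29.10,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
16b,309.26,4.49,5,1,29.10,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
16c,309.26,4.49,5,1,29.10,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
17a,309.26,4.49,5,1,29.10,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
18a,309.26,4.49,5,1,29.10,Yes,0,No,1,WLOGP>5.6,Yes,Yes,Yes,0.55
19a,224.25,3.30,2,0,26.30,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
20a,254.28,3.31,3,0,35.53,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
20b,288.73,3.96,3,0,35.53,Yes,0,Yes,0,,Yes,Yes,Yes,0.55
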