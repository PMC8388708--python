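age_week,feed_g,day_rate,night_rate,ratio,ph_mean,ph_sd,mc_mean,mc_sd
10,60,7.0,3.7,2.19,7.5,0.2,73.3,3.9
11,63,7.2,3.9,2.16,7.9,0.3,71.5,2.8
12,67,7.6,3.9,2.12,7.6,0.3,78.7,1.6
13,70,8.0,4.5,2.24,7.3,0.2,79.3,1.1
14,74,8.2,4.6,2.17,7.1,0.1,76.1,1.9
15,78,8.4,4.8,2.11,7.5,0.1,74.5,3.5
16,83,8.5,5.1,2.05,7.6,0.3,81.6,2.9
17,88,8.9,5.0,2.03,7.3,0.1,75.4,1.8
18,93,9.2,5.4,2.01,7.7,0.3,74.5,3.4
19,98,9.6,5.3,1.95,6.9,0.3,78.9,2.3
20,103,10.1,5.6,1.96,7.3,0.2,81.2,1.7
21,108,10.6,5.8,1.97,7.1,0.2,77.4,3.9
22,110,10.9,5.5,2.01,7.0,0.2,72.7,4.0
23,112,11.0,5.9,1.93,7.3,0.1,77.3,3.3
24,114,11.1,5.8,1.94,7.1,0.3,79.1,1.1
25,116,11.4,6.0,1.95,7.4,0.3,72.9,1.5
26,118,11.6,6.1,2.01,7.2,0.2,82.3,2.1
27,120,11.8,6.0,2.02,7.1,0.2,74.9,2.9
28,120,11.7,6.2,2.01,6.8,0.1,75.8,1.5
29,120,11.9,6.1,2.04,6.9,0.1,76.8,2.4
30,120,11.8,6.2,2.03,7.0,0.2,79.2,2.6
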