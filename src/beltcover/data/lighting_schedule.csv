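age_week,daylength_h,target_weight_g
10,13,1140
11,13,1230
12,13,1320
13,14,1410
14,14,1500
15,14,1590
16,14,1680
17,15,1770
18,15,1860
19,15,1950
20,15,2040
21,16,2130
22,16,2220
23,16,2300
24,16,2380
25,17,2460
26,17,2540
27,17,2630
28,17,2700
29,17,2770
30,17,2840
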