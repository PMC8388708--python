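# synthetic: simulated 21-week mean MCP curve (6 plates/week)
hour,mcp_mean_pct,mcp_sd_pct,n_series
1,4.343097470238096,1.077565261282112,126
2,8.359754712301587,1.424393301418556,126
3,12.249362599206355,1.7284245688726165,126
4,16.070662202380948,1.956757877067136,126
5,19.733402529761896,1.9473589209755955,126
6,23.08956349206349,2.084869567708825,126
7,26.41120833333333,2.1622029598016463,126
8,29.605093501984133,2.1268913626886605,126
9,32.64283159722223,2.2572752922632326,126
10,35.4977849702381,2.2807368036674553,126
11,38.25725049603172,2.2718822858513996,126
12,41.00003149801588,2.3935381993227356,126
13,43.45761061507936,2.3608437491467256,126
14,45.75599379960316,2.435320384210322,126
15,47.801041914682536,2.4736507739642217,126
16,49.55081547619046,2.6429503702787724,126
17,50.95712524801585,2.6517473733355756,126
18,52.107009920634916,2.6319046301871944,126
19,53.20849851190475,2.6098618244161225,126
20,54.306211557539676,2.5238901490468377,126
21,55.362709573412715,2.4895812292339814,126
22,56.381902529761895,2.4315192630284144,126
23,57.396245783730144,2.431263936673915,126
24,58.3745260416667,2.4316243014660937,126
25,60.17177331349206,2.4661803938255678,126
26,61.89099900793653,2.3805378644723367,126
27,63.56208903769844,2.3990052315200203,126
28,65.18122569444444,2.361081154418091,126
29,66.738550843254,2.284751162967938,126
30,68.14723834325397,2.256837476307188,126
31,69.43994246031747,2.266050551801293,126
32,70.76678794642856,2.1392775464095304,126
33,72.04027876984127,2.14051130668733,126
34,73.259878968254,2.0684094306071876,126
35,74.3975659722222,1.981846200938748,126
36,75.51239409722226,1.889716255321038,126
37,76.62764806547624,1.8031170609841634,126
38,77.52604414682543,1.7798990485956545,126
39,78.35025297619045,1.7594784362463984,126
40,79.07366220238096,1.805090792538712,126
41,79.6616140873016,1.7799455842951601,126
42,80.15633878968255,1.748573408540036,126
43,80.64863467261908,1.7138492457470935,126
44,81.0959047619048,1.6729510484603671,126
45,81.53168849206345,1.6895945931778673,126
46,81.96407564484124,1.655483617270915,126
47,82.36435119047617,1.6464357343849843,126
48,82.76170486111111,1.600576067167671,126
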