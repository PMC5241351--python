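mole_percent,delta_q_uJ,grad_9_35_mJ_per_bar_K,grad_35_61_mJ_per_bar_K,viscosity_mm2_per_s
0.0,70,,,0.89
1.0,-403,-4.8,-3.5,
1.5,-737,-5.1,-4.8,
2.0,-1243,-5.6,-5.6,
2.5,-1683,-5.6,-6.0,
5.0,-5214,-2.2,-3.0,
8.0,-12156,20.3,9.8,
10.0,-15324,34.1,18.4,2.59
12.0,-17469,45.3,22.0,
13.0,-18080,47.6,21.4,
14.0,-18923,49.1,21.1,
15.0,-19560,47.6,21.3,
16.0,-19785,47.8,20.0,
20.0,-21630,44.1,15.8,3.31
40.0,-26242,30.7,3.6,3.46
60.0,-28436,17.5,-6.7,3.02
80.0,-30103,13.9,-11.2,2.70
100.0,-28808,,-20.4,2.65
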