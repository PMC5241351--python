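mole_percent,pct_PP,pct_PW,pct_none,non_ideality
1,1.42,90.41,5.75,0.076
2.5,2.71,88.83,6.30,0.0615
5,10.33,81.29,6.63,0.081
10,30.54,60.95,7.27,0.213
15,36.68,54.9,7.33,0.295
20,43.52,48.31,7.24,0.369
25,50.37,41.3,7.58,0.431
30,50.77,41.02,7.47,0.436
35,57.01,34.84,7.46,0.422
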