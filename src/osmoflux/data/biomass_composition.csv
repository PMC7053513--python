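condition,precursor,demand_mmol_per_gCDW
0.0,G6P,0.154
0.0,F6P,0.062
0.0,R5P,0.625
0.0,E4P,0.268
0.0,GAP,0.093
0.0,PG3,1.260
0.0,PEP,0.438
0.0,PYR,2.410
0.0,ACCOA,2.370
0.0,OAA,1.120
0.0,GLU,0.860
0.0,PRO,0.210
0.0,PHB,0.698
0.6,G6P,0.146
0.6,F6P,0.059
0.6,R5P,0.531
0.6,E4P,0.255
0.6,GAP,0.088
0.6,PG3,1.197
0.6,PEP,0.416
0.6,PYR,2.290
0.6,ACCOA,2.252
0.6,OAA,1.064
0.6,GLU,0.817
0.6,PRO,0.750
0.6,PHB,1.674
1.2,G6P,0.131
1.2,F6P,0.053
1.2,R5P,0.438
1.2,E4P,0.228
1.2,GAP,0.079
1.2,PG3,1.071
1.2,PEP,0.372
1.2,PYR,2.049
1.2,ACCOA,2.015
1.2,OAA,0.952
1.2,GLU,0.731
1.2,PRO,1.680
1.2,PHB,3.430
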