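parameter,condition_M,value,sd
mu,0.0,1.19,0.02
mu,0.3,0.88,0.01
mu,0.6,0.69,0.01
mu,0.9,0.57,0.01
mu,1.2,0.39,0.00
mu,1.8,0.24,0.00
Y_XS,0.0,83.1,1.1
Y_XS,0.3,77.2,0.9
Y_XS,0.6,74.6,1.1
Y_XS,0.9,70.7,1.3
Y_XS,1.2,67.3,0.9
Y_XS,1.8,58.7,0.7
q_s,0.0,14.4,0.3
q_s,0.3,11.5,0.2
q_s,0.6,9.3,0.2
q_s,0.9,8.0,0.2
q_s,1.2,5.8,0.1
q_s,1.8,4.0,0.1
Y_acetate,0.0,669,21
Y_acetate,0.3,526,24
Y_acetate,0.6,490,19
Y_acetate,0.9,422,41
Y_acetate,1.2,346,26
Y_acetate,1.8,253,22
Y_pyruvate,0.0,6.4,0.3
Y_pyruvate,0.3,7.6,0.4
Y_pyruvate,0.6,2.9,0.1
Y_pyruvate,0.9,1.7,0.1
Y_pyruvate,1.2,2.2,0.2
Y_pyruvate,1.8,20.1,1.6
Y_lactate,0.0,4.4,0.3
Y_lactate,0.3,3.6,0.2
Y_lactate,0.6,8.3,0.4
Y_lactate,0.9,15.0,0.6
Y_lactate,1.2,20.3,0.6
Y_lactate,1.8,37.7,2.0
Y_succinate,0.0,62.6,3.2
Y_succinate,0.3,22.7,1.0
Y_succinate,0.6,14.7,0.7
Y_succinate,0.9,13.4,0.6
Y_succinate,1.2,10.0,0.4
Y_succinate,1.8,5.8,0.6
Y_oxoglutarate,0.0,9.7,0.4
Y_oxoglutarate,0.3,2.3,0.1
Y_oxoglutarate,0.6,1.3,0.1
Y_oxoglutarate,0.9,0.7,0.1
Y_oxoglutarate,1.2,1.2,0.1
Y_oxoglutarate,1.8,1.6,0.1
AEC,0.0,0.8336,
AEC,0.6,0.7659,
AEC,1.2,0.8612,
NADH_NAD,0.0,0.0079,
NADH_NAD,0.6,0.0260,
NADH_NAD,1.2,0.0191,
NADPH_NADP,0.0,0.5162,
NADPH_NADP,0.6,0.4330,
NADPH_NADP,1.2,1.0551,
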