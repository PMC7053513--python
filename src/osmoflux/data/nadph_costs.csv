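precursor,nadph_mmol_per_mmol
G6P,0.0
F6P,0.0
R5P,0.4
E4P,1.0
GAP,0.3
PG3,0.6
PEP,0.3
PYR,0.8
ACCOA,0.6
OAA,0.9
GLU,1.0
PRO,0.0
PHB,0.0
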