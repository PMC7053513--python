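amino_acid,fragment,emus,n_backbone,C,H,N,O,Si,S
Ala,M-57,PYR:123,3,11,26,1,2,2,0
Ala,M-159,PYR:23,2,8,20,1,0,1,0
Gly,M-57,PG3:12,2,10,24,1,2,2,0
Gly,M-159,PG3:2,1,7,18,1,0,1,0
Val,M-57,PYR:123+PYR:23,5,13,30,1,2,2,0
Val,M-159,PYR:23+PYR:23,4,10,24,1,0,1,0
Leu,M-57,ACCOA:12+PYR:23+PYR:23,6,14,32,1,2,2,0
Leu,M-159,ACCOA:2+PYR:23+PYR:23,5,11,26,1,0,1,0
Ile,M-57,OAA:1234+PYR:23,6,14,32,1,2,2,0
Ile,M-159,OAA:234+PYR:23,5,11,26,1,0,1,0
Ser,M-57,PG3:123,3,17,40,1,3,3,0
Ser,M-159,PG3:23,2,14,34,1,1,2,0
Thr,M-57,OAA:1234,4,18,42,1,3,3,0
Thr,M-159,OAA:234,3,15,36,1,1,2,0
Asp,M-57,OAA:1234,4,18,40,1,4,3,0
Asp,M-159,OAA:234,3,15,34,1,2,2,0
Glu,M-57,GLU:12345,5,19,42,1,4,3,0
Glu,M-159,GLU:2345,4,16,36,1,2,2,0
Pro,M-57,PRO:12345,5,13,28,1,2,2,0
Pro,M-159,PRO:2345,4,10,22,1,0,1,0
Phe,M-57,PEP:123+PEP:23+E4P:1234,9,17,30,1,2,2,0
Phe,M-159,PEP:23+PEP:23+E4P:1234,8,14,24,1,0,1,0
Tyr,M-57,PEP:123+PEP:23+E4P:1234,9,23,44,1,3,3,0
Tyr,M-159,PEP:23+PEP:23+E4P:1234,8,20,38,1,1,2,0
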