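reaction_id,equation,reversible,kind,cofactors
upt,GLC (abcdef) = G6P (abcdef),0,measured-exchange,ATP:-1
pgi,G6P (abcdef) = F6P (abcdef),1,free,
pfk,F6P (abcdef) = FBP (abcdef),0,free,ATP:-1
fba,FBP (abcdef) = DHAP (cba) + GAP (def),1,free,
tpi,DHAP (abc) = GAP (abc),1,free,
gapdh,GAP (abc) = PG3 (abc),1,free,NADH:+1;ATP:+1
eno,PG3 (abc) = PEP (abc),1,free,
pyk,PEP (abc) = PYR (abc),0,free,ATP:+1
zwf,G6P (abcdef) = PG6 (abcdef),0,free,NADPH:+1
gnd,PG6 (abcdef) = RU5P (bcdef) + CO2 (a),0,free,NADPH:+1
rpe,RU5P (abcde) = X5P (abcde),1,free,
rpi,RU5P (abcde) = R5P (abcde),1,free,
tkt1,X5P (abcde) + R5P (fghij) = S7P (abfghij) + GAP (cde),1,free,
tkt2,X5P (abcde) + E4P (fghi) = F6P (abfghi) + GAP (cde),1,free,
tal,S7P (abcdefg) + GAP (hij) = E4P (defg) + F6P (abchij),1,free,
pdh,PYR (abc) = ACCOA (bc) + CO2 (a),0,free,NADH:+1
cs,OAA (abcd) + ACCOA (ef) = CIT (dcbfea),0,free,
icd,CIT (abcdef) = AKG (abcde) + CO2 (f),0,free,NADPH:+1
akgdh,AKG (abcde) = SUC (bcde) + CO2 (a),0,free,NADH:+1;ATP:+1
sdh,SUC (abcd|dcba) = FUM (abcd),1,free,FADH2:+1
fum,FUM (abcd|dcba) = MAL (abcd),1,free,
mdh,MAL (abcd) = OAA (abcd),1,free,NADH:+1
pepc,PEP (abc) + CO2 (d) = OAA (abcd),0,free,
pyca,PYR (abc) + CO2 (d) = OAA (abcd),0,constrained,ATP:-1
pox,PYR (abc) = ACE (bc) + CO2 (a),0,constrained,FADH2:+1
pta,ACCOA (ab) = ACE (ab),0,free,ATP:+1
ace_out,ACE (ab) = ACE_ex (ab),0,measured-exchange,
ldh,PYR (abc) = LAC (abc),0,free,NADH:-1
lac_out,LAC (abc) = LAC_ex (abc),0,measured-exchange,
pyr_out,PYR (abc) = PYR_ex (abc),0,measured-exchange,
suc_out,SUC (abcd) = SUC_ex (abcd),0,measured-exchange,
akg_out,AKG (abcde) = AKG_ex (abcde),0,measured-exchange,
gdh,AKG (abcde) + NH4 = GLU (abcde),0,free,NADPH:-1;ATP:-1
proJ_proA,GLU (abcde) = GSA (abcde),0,free,ATP:-1;NADPH:-1
p5c_cyc,GSA (abcde) = P5C (abcde),0,free,
proH,P5C (abcde) = PRO (abcde),0,free,NADPH:-1
phaA,ACCOA (ab) + ACCOA (cd) = AACOA (abcd),0,free,
phaB,AACOA (abcd) = HBCOA (abcd),0,free,NADPH:-1
phaC,HBCOA (abcd) = PHB (abcd),0,biomass-drain,
bm_g6p,G6P (abcdef) = BM_G6P (abcdef),0,biomass-drain,
bm_f6p,F6P (abcdef) = BM_F6P (abcdef),0,biomass-drain,
bm_r5p,R5P (abcde) = BM_R5P (abcde),0,biomass-drain,
bm_e4p,E4P (abcd) = BM_E4P (abcd),0,biomass-drain,
bm_gap,GAP (abc) = BM_GAP (abc),0,biomass-drain,
bm_pg3,PG3 (abc) = BM_PG3 (abc),0,biomass-drain,
bm_pep,PEP (abc) = BM_PEP (abc),0,biomass-drain,
bm_pyr,PYR (abc) = BM_PYR (abc),0,biomass-drain,
bm_accoa,ACCOA (ab) = BM_ACCOA (ab),0,biomass-drain,
bm_oaa,OAA (abcd) = BM_OAA (abcd),0,biomass-drain,
bm_glu,GLU (abcde) = BM_GLU (abcde),0,biomass-drain,
bm_pro,PRO (abcde) = BM_PRO (abcde),0,biomass-drain,
co2_out,CO2 (a) = CO2_ex (a),0,free,
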