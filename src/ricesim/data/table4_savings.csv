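sex,age_band,row_kind,savings_s1_usd,savings_s1_pct,savings_s2_usd,savings_s2_pct
male,40-79,sex_total,23535925,0.2,60507861,0.6
male,40-49,age,1328875,0.3,3200548,0.6
male,50-59,age,5302819,0.4,13291622,0.9
male,60-69,age,11077131,0.3,28737698,0.8
male,70-79,age,5827099,0.1,15277992,0.3
female,40-79,sex_total,7786800,0.1,19972435,0.3
female,40-49,age,280164,0.2,665984,0.4
female,50-59,age,1222818,0.2,3037052,0.5
female,60-69,age,3435131,0.2,8860798,0.5
female,70-79,age,2848687,0.1,7408601,0.2
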