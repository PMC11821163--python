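sex,age_band,row_kind,averted_cases_s1_n,averted_cases_s1_pct,averted_cases_s2_n,averted_cases_s2_pct,averted_deaths_s1_n,averted_deaths_s1_pct,averted_deaths_s2_n,averted_deaths_s2_pct
male,40-79,sex_total,31742,1.5,82445,4.0,384,0.01,820,0.02
male,40-49,age,7117,1.7,18440,4.5,27,0.02,58,0.04
male,50-59,age,10838,1.6,28136,4.2,84,0.02,179,0.05
male,60-69,age,9916,1.4,25822,3.7,177,0.02,377,0.04
male,70-79,age,3871,1.3,10047,3.4,96,0.01,206,0.01
female,40-79,sex_total,17671,1.0,46922,2.7,121,0.01,261,0.02
female,40-49,age,3088,1.2,8164,3.2,8,0.01,17,0.02
female,50-59,age,5347,1.0,14208,2.8,24,0.01,51,0.03
female,60-69,age,5977,1.0,15916,2.6,50,0.01,107,0.03
female,70-79,age,3258,1.0,8635,2.6,39,0.00,85,0.01
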