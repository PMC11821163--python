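sex,age_band,row_kind,population,t2d_incidence_n,t2d_incidence_pct,deaths_n,deaths_pct,expenditure_usd
male,40-79,sex_total,32797470,2064200,6.3,3354874,10.2,10061421208
male,40-49,age,9373569,408411,4.4,150248,1.6,495187931
male,50-59,age,8160860,668028,8.2,358224,4.4,1489398961
male,60-69,age,7929684,695282,8.8,959652,12.1,3645371892
male,70-79,age,7333357,292479,4.0,1886749,25.7,4431462425
female,40-79,sex_total,34158646,1721478,5.0,1715339,5.0,5709993001
female,40-49,age,9146186,258847,2.8,86793,0.9,168554681
female,50-59,age,8116993,512116,6.3,179677,2.2,568550514
female,60-69,age,8301898,623188,7.5,421289,5.1,1862203904
female,70-79,age,8593569,327327,3.8,1027580,12.0,3110683903
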