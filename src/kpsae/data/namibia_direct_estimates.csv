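region_id,population,method,point,ci_lower,ci_upper,year
zambezi,FSW,mapping,284,142,426,2013
ohangwena,FSW,mapping,158,79,237,2013
erongo,FSW,mapping,322,161,483,2013
khomas,FSW,mapping,528,264,792,2013
zambezi,FSW,key_informant,300,50,4300,2013
ohangwena,FSW,key_informant,100,30,800,2013
erongo,FSW,key_informant,330,200,1000,2013
khomas,FSW,key_informant,100,50,1700,2013
zambezi,FSW,unique_object_multiplier,5299,3500,8575,2013
ohangwena,FSW,unique_object_multiplier,1494,1249,1822,2013
erongo,FSW,unique_object_multiplier,2352,1597,4557,2013
khomas,FSW,unique_object_multiplier,5240,3373,11706,2013
zambezi,FSW,wisdom_of_crowds,300,100,1000,2013
ohangwena,FSW,wisdom_of_crowds,500,300,1000,2013
erongo,FSW,wisdom_of_crowds,700,200,2000,2013
khomas,FSW,wisdom_of_crowds,600,200,1500,2013
zambezi,FSW,literature_review,84,47,251,2013
ohangwena,FSW,literature_review,85,47,254,2013
erongo,FSW,literature_review,241,134,723,2013
khomas,FSW,literature_review,1582,1055,2110,2013
zambezi,FSW,stakeholder_consensus,800,380,2000,2013
ohangwena,FSW,stakeholder_consensus,900,775,2750,2013
erongo,FSW,stakeholder_consensus,900,825,1500,2013
khomas,FSW,stakeholder_consensus,3000,1800,3400,2013
zambezi,FSW,ss_pse,674,318,2426,2019
ohangwena,FSW,ss_pse,900,775,2750,2019
erongo,FSW,ss_pse,1057,576,3369,2019
khomas,FSW,ss_pse,2196,1651,2382,2019
karas,MSM,mapping,282,141,423,2013
oshana,MSM,mapping,78,39,117,2013
erongo,MSM,mapping,488,244,732,2013
khomas,MSM,mapping,460,230,690,2013
karas,MSM,key_informant,1132,200,2948,2013
oshana,MSM,key_informant,2000,250,5184,2013
erongo,MSM,key_informant,100,70,300,2013
khomas,MSM,key_informant,300,100,1600,2013
karas,MSM,unique_object_multiplier,1714,1292,2359,2013
oshana,MSM,unique_object_multiplier,3538,2379,5632,2013
erongo,MSM,unique_object_multiplier,2982,2013,5808,2013
khomas,MSM,unique_object_multiplier,2229,1699,3240,2013
karas,MSM,wisdom_of_crowds,100,40,400,2013
oshana,MSM,wisdom_of_crowds,150,50,500,2013
erongo,MSM,wisdom_of_crowds,70,40,250,2013
khomas,MSM,wisdom_of_crowds,400,,,2013
karas,MSM,literature_review,84,24,138,2013
oshana,MSM,literature_review,157,45,259,2013
erongo,MSM,literature_review,427,122,701,2013
khomas,MSM,literature_review,1207,345,1983,2013
karas,MSM,stakeholder_consensus,500,300,650,2013
oshana,MSM,stakeholder_consensus,500,350,800,2013
erongo,MSM,stakeholder_consensus,610,475,658,2013
khomas,MSM,stakeholder_consensus,2416,850,4000,2013
erongo,MSM,ss_pse,670,410,1610,2019
khomas,MSM,ss_pse,2416,850,4000,2019
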