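population,region_id,variant,data_mode,estimate
FSW,zambezi,simple,pre_program,175
FSW,zambezi,simple,post_program,256
FSW,zambezi,stratified_hiv,pre_program,231
FSW,zambezi,stratified_hiv,post_program,404
FSW,zambezi,stratified_density,pre_program,749
FSW,zambezi,stratified_density,post_program,311
FSW,ohangwena,simple,pre_program,129
FSW,ohangwena,simple,post_program,189
FSW,ohangwena,stratified_hiv,pre_program,171
FSW,ohangwena,stratified_hiv,post_program,299
FSW,ohangwena,stratified_density,pre_program,680
FSW,ohangwena,stratified_density,post_program,230
FSW,erongo,simple,pre_program,985
FSW,erongo,simple,post_program,1441
FSW,erongo,stratified_hiv,pre_program,695
FSW,erongo,stratified_hiv,post_program,609
FSW,erongo,stratified_density,pre_program,1607
FSW,erongo,stratified_density,post_program,523
FSW,khomas,simple,pre_program,2751
FSW,khomas,simple,post_program,4022
FSW,khomas,stratified_hiv,pre_program,1941
FSW,khomas,stratified_hiv,post_program,1701
FSW,khomas,stratified_density,pre_program,1608
FSW,khomas,stratified_density,post_program,4876
FSW,hardap,simple,pre_program,284
FSW,hardap,simple,post_program,415
FSW,hardap,stratified_hiv,pre_program,200
FSW,hardap,stratified_hiv,post_program,175
FSW,hardap,stratified_density,pre_program,638
FSW,hardap,stratified_density,post_program,151
FSW,karas,simple,pre_program,278
FSW,karas,simple,post_program,406
FSW,karas,stratified_hiv,pre_program,196
FSW,karas,stratified_hiv,post_program,172
FSW,karas,stratified_density,pre_program,716
FSW,karas,stratified_density,post_program,147
FSW,kavango,simple,pre_program,368
FSW,kavango,simple,post_program,538
FSW,kavango,stratified_hiv,pre_program,260
FSW,kavango,stratified_hiv,post_program,227
FSW,kavango,stratified_density,pre_program,1766
FSW,kavango,stratified_density,post_program,195
FSW,kunene,simple,pre_program,140
FSW,kunene,simple,post_program,204
FSW,kunene,stratified_hiv,pre_program,99
FSW,kunene,stratified_hiv,post_program,86
FSW,kunene,stratified_density,pre_program,698
FSW,kunene,stratified_density,post_program,74
FSW,omaheke,simple,pre_program,103
FSW,omaheke,simple,post_program,151
FSW,omaheke,stratified_hiv,pre_program,73
FSW,omaheke,stratified_hiv,post_program,64
FSW,omaheke,stratified_density,pre_program,445
FSW,omaheke,stratified_density,post_program,55
FSW,omusati,simple,pre_program,74
FSW,omusati,simple,post_program,107
FSW,omusati,stratified_hiv,pre_program,97
FSW,omusati,stratified_hiv,post_program,170
FSW,omusati,stratified_density,pre_program,672
FSW,omusati,stratified_density,post_program,130
FSW,oshana,simple,pre_program,512
FSW,oshana,simple,post_program,749
FSW,oshana,stratified_hiv,pre_program,361
FSW,oshana,stratified_hiv,post_program,317
FSW,oshana,stratified_density,pre_program,619
FSW,oshana,stratified_density,post_program,908
FSW,oshikoto,simple,pre_program,125
FSW,oshikoto,simple,post_program,183
FSW,oshikoto,stratified_hiv,pre_program,165
FSW,oshikoto,stratified_hiv,post_program,288
FSW,oshikoto,stratified_density,pre_program,1897
FSW,oshikoto,stratified_density,post_program,222
FSW,otjozondjupa,simple,pre_program,428
FSW,otjozondjupa,simple,post_program,626
FSW,otjozondjupa,stratified_hiv,pre_program,302
FSW,otjozondjupa,stratified_hiv,post_program,265
FSW,otjozondjupa,stratified_density,pre_program,1052
FSW,otjozondjupa,stratified_density,post_program,227
MSM,zambezi,simple,pre_program,114
MSM,zambezi,simple,post_program,59
MSM,zambezi,stratified_hiv,pre_program,165
MSM,zambezi,stratified_hiv,post_program,63
MSM,zambezi,stratified_density,pre_program,421
MSM,zambezi,stratified_density,post_program,35
MSM,ohangwena,simple,pre_program,81
MSM,ohangwena,simple,post_program,42
MSM,ohangwena,stratified_hiv,pre_program,117
MSM,ohangwena,stratified_hiv,post_program,45
MSM,ohangwena,stratified_density,pre_program,789
MSM,ohangwena,stratified_density,post_program,25
MSM,erongo,simple,pre_program,854
MSM,erongo,simple,post_program,439
MSM,erongo,stratified_hiv,pre_program,741
MSM,erongo,stratified_hiv,post_program,403
MSM,erongo,stratified_density,pre_program,1167
MSM,erongo,stratified_density,post_program,612
MSM,khomas,simple,pre_program,1991
MSM,khomas,simple,post_program,1024
MSM,khomas,stratified_hiv,pre_program,1728
MSM,khomas,stratified_hiv,post_program,941
MSM,khomas,stratified_density,pre_program,2249
MSM,khomas,stratified_density,post_program,621
MSM,hardap,simple,pre_program,215
MSM,hardap,simple,post_program,110
MSM,hardap,stratified_hiv,pre_program,186
MSM,hardap,stratified_hiv,post_program,101
MSM,hardap,stratified_density,pre_program,455
MSM,hardap,stratified_density,post_program,154
MSM,karas,simple,pre_program,196
MSM,karas,simple,post_program,100
MSM,karas,stratified_hiv,pre_program,282
MSM,karas,stratified_hiv,post_program,109
MSM,karas,stratified_density,pre_program,452
MSM,karas,stratified_density,post_program,140
MSM,kavango,simple,pre_program,215
MSM,kavango,simple,post_program,111
MSM,kavango,stratified_hiv,pre_program,310
MSM,kavango,stratified_hiv,post_program,119
MSM,kavango,stratified_density,pre_program,802
MSM,kavango,stratified_density,post_program,154
MSM,kunene,simple,pre_program,96
MSM,kunene,simple,post_program,49
MSM,kunene,stratified_hiv,pre_program,84
MSM,kunene,stratified_hiv,post_program,45
MSM,kunene,stratified_density,pre_program,437
MSM,kunene,stratified_density,post_program,69
MSM,omaheke,simple,pre_program,78
MSM,omaheke,simple,post_program,40
MSM,omaheke,stratified_hiv,pre_program,67
MSM,omaheke,stratified_hiv,post_program,37
MSM,omaheke,stratified_density,pre_program,346
MSM,omaheke,stratified_density,post_program,56
MSM,omusati,simple,pre_program,43
MSM,omusati,simple,post_program,22
MSM,omusati,stratified_hiv,pre_program,62
MSM,omusati,stratified_hiv,post_program,24
MSM,omusati,stratified_density,pre_program,801
MSM,omusati,stratified_density,post_program,13
MSM,oshana,simple,pre_program,313
MSM,oshana,simple,post_program,161
MSM,oshana,stratified_hiv,pre_program,452
MSM,oshana,stratified_hiv,post_program,174
MSM,oshana,stratified_density,pre_program,721
MSM,oshana,stratified_density,post_program,97
MSM,oshikoto,simple,pre_program,96
MSM,oshikoto,simple,post_program,49
MSM,oshikoto,stratified_hiv,pre_program,139
MSM,oshikoto,stratified_hiv,post_program,53
MSM,oshikoto,stratified_density,pre_program,804
MSM,oshikoto,stratified_density,post_program,30
MSM,otjozondjupa,simple,pre_program,313
MSM,otjozondjupa,simple,post_program,161
MSM,otjozondjupa,stratified_hiv,pre_program,272
MSM,otjozondjupa,stratified_hiv,post_program,148
MSM,otjozondjupa,stratified_density,pre_program,721
MSM,otjozondjupa,stratified_density,post_program,224
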