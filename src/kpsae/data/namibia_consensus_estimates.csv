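region_id,population,point,ci_lower,ci_upper
zambezi,FSW,208,88,420
ohangwena,FSW,302,189,453
erongo,FSW,387,194,648
khomas,FSW,1480,1099,1779
karas,MSM,134,15,294
oshana,MSM,75,23,147
erongo,MSM,404,209,562
khomas,MSM,511,143,958
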