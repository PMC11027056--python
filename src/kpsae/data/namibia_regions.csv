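region_id,name
zambezi,Zambezi
ohangwena,Ohangwena
erongo,Erongo
khomas,Khomas
hardap,Hardap
karas,Karas
kavango,Kavango
kunene,Kunene
omaheke,Omaheke
omusati,Omusati
oshana,Oshana
oshikoto,Oshikoto
otjozondjupa,Otjozondjupa
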