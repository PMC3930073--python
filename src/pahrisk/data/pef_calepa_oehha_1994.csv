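analyte,factor
Naphthalene,0.0
Acenaphthylene,0.0
Acenaphthene,0.0
Fluorene,0.0
Phenanthrene,0.0
Anthracene,0.0
Fluoranthene,0.0
Pyrene,0.0
Benz[a]anthracene,0.1
Chrysene,0.01
Benzo[b]fluoranthene,0.1
Benzo[k]fluoranthene,0.1
Benzo[a]pyrene,1.0
"Indeno[1,2,3-cd]pyrene",0.1
"Dibenz[a,h]anthracene",1.1
"Benzo[g,h,i]perylene",0.0
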