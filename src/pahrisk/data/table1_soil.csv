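analyte,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18
distance_km,21.7,0.1,11.8,0.1,1.9,3.3,32,30.6,8.7,34,10.8,18.9,1.7,6.4,9.9,26,10.4,0.1
Naphthalene,-,1.9,5.1,-,27.5,-,26.4,-,-,-,100.5,-,-,-,-,-,-,-
Acenaphthylene,-,-,-,38.2,39.9,30.4,-,24.7,22.5,22.3,15.9,22.4,20.5,6.3,17.5,30.9,17.2,93.5
Acenaphthene,-,-,-,1.1,1.9,-,-,-,0.5,3.8,-,-,18.1,8.7,-,11,39.7,-
Fluorene,-,0.6,-,-,20.5,-,0.4,-,-,-,0.1,1,4.9,2.7,-,-,2.4,1.4
Phenanthrene,-,5.9,-,-,23.5,-,1.4,-,-,-,1.9,12.5,29.2,35.4,4.3,-,33.1,5.4
Anthracene,-,-,-,-,7.8,-,-,-,-,-,3.4,-,-,-,0.4,2,6.1,0.6
Fluoranthene,-,11.8,-,0.7,7.6,-,4.2,0.8,-,0.7,13.8,5.8,5.9,154.2,18.4,-,14,2
Pyrene,-,46.5,-,-,-,-,6.1,2,-,-,13.5,2.6,7,66.1,18.6,-,15.3,6.2
Benz[a]anthracene,-,4.4,-,-,-,-,0.6,-,-,0.6,5.2,0.6,-,5.3,9,-,3.8,0.1
Chrysene,0.7,122.1,0.3,1,4.3,0.7,5.2,1.1,-,2.7,10.8,6,6,33,19.8,-,8.1,1.2
Benzo[b]fluoranthene,0.6,46.2,-,0.9,-,0.4,1.7,-,-,1,10.5,2.9,3.5,52.9,25.3,-,8.6,3.3
Benzo[k]fluoranthene,-,11.8,-,-,-,-,-,-,-,-,4.2,0.3,-,196.5,9.5,-,1.9,-
Benzo[a]pyrene,-,18.8,-,-,-,-,0.6,-,-,0.6,7.1,0.6,-,17.9,19.1,-,3.8,-
"Indeno[1,2,3-cd]pyrene",-,26.2,-,-,-,-,-,-,-,-,6.5,-,-,66.8,16.3,-,3.3,-
"Dibenz[a,h]anthracene",-,8,-,-,-,-,-,-,-,-,-,-,-,-,2.3,-,-,-
"Benzo[g,h,i]perylene",1.9,35.4,-,-,-,-,-,-,-,-,5.7,-,-,20.9,16.4,-,4.8,2.6
sum_pah,3.2,339.6,5.4,41.9,133,31.5,46.6,28.6,23,31.7,199.1,54.7,95.1,666.7,176.9,43.9,162.1,116.3
bap_equivalents,0.7,79.0,3.0E-03,1.3,0.6,0.7,2.4,0.3,0.2,1.5,19.7,3.5,3.8,99.8,50.7,0.3,13.8,4.3
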