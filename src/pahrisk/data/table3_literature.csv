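# BaP-equivalent soil concentrations (mg/kg) and printed lifetime cancer risks
# for petroleum-extraction regions. The Cold Lake row prints rounded
# concentrations (0.1 / 0.02); the *_mg_per_kg columns carry the unrounded
# measured values that reproduce the printed risks.
location,n,max_printed,mean_printed,max_mg_per_kg,mean_mg_per_kg,risk_max_printed,risk_mean_printed
Niger Delta Nigeria,8,5.3,2.0,5.3,2.0,4.05E-06,1.50E-06
Texas USA,3,14.7,11.0,14.7,11.0,1.12E-05,8.41E-06
Vojvodina Serbia,7,8.2,2.6,8.2,2.6,6.28E-06,1.98E-06
Mathura India,29,,0.34,,0.34,,2.59E-07
Cold Lake Canada,18,0.1,0.02,0.09978,0.0157,7.63E-08,1.20E-08
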