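# Monte Carlo input distributions: field-concentration scenario
# (lognormal Cs from the measured site, lognormal IR, EF fixed at 153 d/yr).
variable,family,mean,sd,min,max
Cs,lognormal,0.0157,0.0297,,
IR,lognormal,52,119,,
EF,uniform,,,153,153
ED,uniform,,,70,70
BW,uniform,,,80,80
AT,uniform,,,25550,25550
CSF,uniform,,,7.3,7.3
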