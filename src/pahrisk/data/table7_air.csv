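# Atmospheric BaP-equivalent concentrations (ug/m3) over the ten 24-h
# sampling periods, and the printed lifetime inhalation cancer risks.
statistic,concentration_ug_per_m3,risk_printed
maximum,2.15E-04,7.10E-10
minimum,1.32E-08,4.37E-14
mean,3.68E-05,1.20E-10
median,7.08E-06,2.34E-11
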