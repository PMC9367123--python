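channel,lower,upper,slope_tol,sd_tol
heart_rate,51,90,1.625,4.875
resp_rate,12,20,0.3333333333333333,1.0
sbp,111,219,4.5,13.5
temperature,36.1,38.0,0.07916666666666666,0.2375
spo2,96,100,0.16666666666666666,0.5
spo2_scale2,88,92,0.16666666666666666,0.5
fio2,0,0,0.05,0.25
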