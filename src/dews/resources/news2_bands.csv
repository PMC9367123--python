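parameter,scale,condition,lower,upper,points
resp_rate,all,,,8,3
resp_rate,all,,9,11,1
resp_rate,all,,12,20,0
resp_rate,all,,21,24,2
resp_rate,all,,25,,3
spo2,1,,,91,3
spo2,1,,92,93,2
spo2,1,,94,95,1
spo2,1,,96,,0
spo2,2,,,83,3
spo2,2,,84,85,2
spo2,2,,86,87,1
spo2,2,,88,92,0
spo2,2,air,93,,0
spo2,2,oxygen,93,94,1
spo2,2,oxygen,95,96,2
spo2,2,oxygen,97,,3
supplemental_o2,all,,0,0,0
supplemental_o2,all,,1,1,2
sbp,all,,,90,3
sbp,all,,91,100,2
sbp,all,,101,110,1
sbp,all,,111,219,0
sbp,all,,220,,3
heart_rate,all,,,40,3
heart_rate,all,,41,50,1
heart_rate,all,,51,90,0
heart_rate,all,,91,110,1
heart_rate,all,,111,130,2
heart_rate,all,,131,,3
consciousness,all,,0,0,0
consciousness,all,,1,4,3
temperature,all,,,35.0,3
temperature,all,,35.1,36.0,1
temperature,all,,36.1,38.0,0
temperature,all,,38.1,39.0,1
temperature,all,,39.1,,2
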