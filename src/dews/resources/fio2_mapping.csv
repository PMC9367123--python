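mode,lower,upper,ordinal
flow,0,2,1
flow,2,5,2
flow,5,9,3
flow,9,15,4
flow,15,,5
concentration,21,28,1
concentration,28,40,2
concentration,40,60,3
concentration,60,80,4
concentration,80,,5
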