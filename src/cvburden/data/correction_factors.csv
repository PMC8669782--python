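risk_factor,factor,n_pairs
bmi,1.10,0
sbp,1.50,0
fpg,1.53,0
tc,1.75,0
non_hdl,1.85,0
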