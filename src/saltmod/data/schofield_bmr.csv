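gender,age_lo,age_hi,slope_mj_per_kg,intercept_mj
M,0,3,0.249,-0.127
M,3,10,0.095,2.110
M,10,18,0.074,2.754
M,18,30,0.063,2.896
M,30,60,0.048,3.653
M,60,200,0.049,2.459
F,0,3,0.244,-0.130
F,3,10,0.085,2.033
F,10,18,0.056,2.898
F,18,30,0.062,2.036
F,30,60,0.034,3.538
F,60,200,0.038,2.755
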