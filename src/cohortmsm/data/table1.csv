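parameter,covariate,est,se,rr,ci_lo,ci_hi
log_lambda12,Baseline intensity,-4.379,0.250,,,
theta1,Age at Ps onset (centered at 40),-0.011,0.009,0.99,0.97,1.01
theta2,Sex (1 = male),0.117,0.298,1.12,0.63,2.01
theta3,HLA-B27 (1 = positive),-0.724,1.012,0.48,0.07,3.52
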