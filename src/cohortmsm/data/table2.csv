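process,transition,covariate,coef,est,se,rr,ci_lo,ci_hi
Marker,1->0,Biologics B(t),eta01,0.335,0.101,1.40,1.15,1.70
Marker,1->0,3-4 swollen joints V1(t),eta02_V1,0.686,0.419,1.99,0.87,4.51
Marker,1->0,>=5 swollen joints V2(t),eta02_V2,-0.074,0.273,0.93,0.54,1.59
Marker,0->1,Biologics B(t),eta11,0.120,0.101,1.13,0.93,1.37
Marker,0->1,3-4 swollen joints V1(t),eta12_V1,0.813,0.461,2.25,0.91,5.57
Marker,0->1,>=5 swollen joints V2(t),eta12_V2,0.157,0.333,1.17,0.61,2.25
Biologics,0->1,Elevated ESR X(t),phi1,0.618,0.197,1.86,1.26,2.73
Biologics,0->1,3-4 swollen joints V1(t),phi2_V1,0.347,0.393,1.42,0.65,3.06
Biologics,0->1,>=5 swollen joints V2(t),phi2_V2,1.004,0.282,2.73,1.57,4.75
Failure,0->1,Elevated ESR X(t),beta1,0.554,0.399,1.74,0.80,3.80
Failure,0->1,Biologics B(t),beta2,1.081,0.297,2.95,1.65,5.27
Failure,0->1,X(t)B(t),beta3,-1.657,0.732,0.19,0.05,0.80
Failure,0->1,3-4 swollen joints V1(t),beta4_V1,0.327,0.528,1.39,0.49,3.91
Failure,0->1,>=5 swollen joints V2(t),beta4_V2,1.334,0.360,3.79,1.87,7.69
Failure,0->1,>5 years disease duration V3,beta4_V3,0.117,0.217,1.12,0.74,1.72
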