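parameter,estimate,rse_pct,bootstrap_median,ci_low,ci_high,shrinkage_pct
kde,0.08150,71.5,0.12844,0.01812,1.08467,
kd,0.00474,17.9,0.00516,0.00385,0.00697,
edk50,41300.0,40.9,28925.7,335.7,108289.8,
k_tol,0.00754,20.3,0.00674,0.00001,0.01569,
omega2_edk50,0.45410,66.4,0.40691,0.00001,2.54713,18.7
sigma2,0.00005,25.8,0.00003,0.00003,0.00006,7.1
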