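label,n_subjects,dose_mg,n_doses,interval_months,followup_months,baseline_bmd
trial01,180,1.0,1,0,24,1.03
trial02,180,2.5,1,0,24,1.03
trial03,616,5.0,6,12,72,0.81
trial04,3875,5.0,3,12,36,0.79
trial05,175,5.0,2,12,24,0.64
trial06,89,5.0,1,0,12,0.93
trial07,458,5.0,1,0,24,0.75
trial08,330,5.0,2,12,24,0.66
trial09,20,5.0,1,0,12,1.06
trial10,91,5.0,1,0,24,1.03
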