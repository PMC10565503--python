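dose_mg,apr_count,total_count,study
1,11,27,apr_s1
4,6,12,apr_s2
5,27,20,apr_s3
5,109,157,apr_s4
5,69,127,apr_s5
5,146,227,apr_s6a
5,158,231,apr_s6b
5,6,12,apr_s2
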