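band_label,rate_per_person_year,source_label
0-44,0.0001,synthetic_high
45-54,0.0015,synthetic_high
55-64,0.003,synthetic_high
65-74,0.008,synthetic_high
75-84,0.018,synthetic_high
85+,0.028,synthetic_high
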