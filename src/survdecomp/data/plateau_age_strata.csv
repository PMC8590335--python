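age_group,cases,deaths
<1 month,5899,31
1-11 months,24983,52
12-59 months,30053,49
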