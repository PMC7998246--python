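her2_status,low_moderate,high
negative,54,24
positive,9,4
unspecified,2,3
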