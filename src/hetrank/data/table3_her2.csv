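her2_status,hypo_intermediate,hyper_intense
negative,11,4
positive,3,7
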