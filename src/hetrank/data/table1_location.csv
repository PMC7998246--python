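location,low_moderate,high
esophagus_ge_junction,62,37
stomach,40,11
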