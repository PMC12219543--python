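across
additionally
comprehensive
crucial
enhancing
exhibited
insights
notably
particularly
within
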