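name: doubling the weekly sample size to 24
batch_size_override: 24
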