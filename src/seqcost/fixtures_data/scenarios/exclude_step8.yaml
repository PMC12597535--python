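name: exclusion of step 8 (molecular tumor board and reporting)
excluded_steps: [8]
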