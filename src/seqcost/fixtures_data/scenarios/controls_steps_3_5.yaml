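name: +10% for controls and sample failure in steps 3-5
step_weights:
  3: 1.10
  4: 1.10
  5: 1.10
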