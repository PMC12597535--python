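name: inclusion of bioinformatic development costs
investments:
  - label: pipeline development (16 months, one bioinformatician)
    total_cost: 1330000
    currency: NOK
    amortization_samples: 1248
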