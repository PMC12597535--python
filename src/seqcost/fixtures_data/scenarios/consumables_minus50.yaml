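name: 50% price reduction in consumables
price_adjustments:
  consumables: -50
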