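name: automated library preparation, 16 weekly samples
variant_inventory: ../automated_inventory.csv
batch_size_override: 16
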