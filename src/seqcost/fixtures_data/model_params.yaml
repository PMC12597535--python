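batch_size: 12
runs_per_year: 52
overhead_rate: 0.2
interest_rate: 0.04
nok_per_usd: 10.7433
nok_per_eur: 11.6276
report_currency: USD
estimate: base
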