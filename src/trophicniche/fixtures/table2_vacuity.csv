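estuary,vacuity_pct
Slack,30.0
Wimereux,20.0
Liane,25.0
Canche,15.8
Authie,19.1
Somme,23.8
Total,22.3
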