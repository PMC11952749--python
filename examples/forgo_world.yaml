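# two pursuit types encountered from an unrewarded default pursuit
pursuits:
  - {label: a, reward: 2.0, duration: 1.0, frequency: 0.5}
  - {label: b, reward: 4.0, duration: 2.0, frequency: 0.25}
default_rate: 0.0
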