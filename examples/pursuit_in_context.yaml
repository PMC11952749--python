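# a pursuit worth 4 reward units over 4 time units, embedded in an
# outside yielding 0.7 reward units over 3 time units per traversal
r_in: 4.0
t_in: 4.0
r_out: 0.7
t_out: 3.0
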