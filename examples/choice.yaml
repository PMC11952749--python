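# smaller-sooner vs larger-later pursuits sharing a 6-time-unit outside
ss: {reward: 2.5, duration: 2.5}
ll: {reward: 5.0, duration: 8.5}
outside: {r_out: 0.0, t_out: 6.0}
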