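# Headline configuration, scaled down for a quick desk run.
# Full scale: N: 2000, generations: 10000.
N: 200
W1: 3.0
W2: 10.0
Pm: 0.001
mut_var: 2.0
F: 0.001
Fd: 0.008
Tf: 0.02
generations: 2000
init_num_languages: 100
seed: 0
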