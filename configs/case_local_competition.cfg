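# Local (within-group) competition, no parenting cost: interference evolves.
n_groups: 50
generations: 5000
replicates: 5
summary_window: 100
lambda_local: 1.0
c2: 0.0
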