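# Global competition with a parenting cost of damage: little interference,
# strongly reduced fighting.
n_groups: 50
generations: 5000
replicates: 5
summary_window: 100
lambda_local: 0.0
c2: 0.04
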