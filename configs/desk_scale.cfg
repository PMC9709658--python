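# Desk-scale study preset: population size and replicate count are reduced;
# every behavioural/selection parameter, the 600-round contest schedule and
# the 5000-generation horizon stay at standard values.
n_groups: 50
generations: 5000
replicates: 5
summary_window: 100
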