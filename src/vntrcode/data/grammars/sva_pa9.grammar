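# Young orangutan subfamily (illustrative): C-type amplification scaffolded
# by Q-type RUs; 3' array distinct from the internal one.
name: SVA_PA_9
prefix: A B C A Q
interior: motif Q C*
interior_copy_range: 2 5
interior_repeats: 2 5
suffix: R T
mutation_rate: 0.005
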