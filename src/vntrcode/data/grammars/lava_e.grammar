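# Young LAVA subfamily: ANBB 5' array; O/P types in the terminal array;
# no organized interior.
name: LAVA_E
prefix: A N B B
interior: random B C D
interior_len_range: 6 16
suffix: O P C.TT
mutation_rate: 0.005
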