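# Oldest human SVA subfamily: short 5' array, no organized interior.
name: SVA_A
prefix: A B C A
interior: random A B C
interior_len_range: 2 8
suffix: T
mutation_rate: 0.005
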