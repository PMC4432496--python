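# SVA2-like ancestral elements: unorganized mix of the two dominant
# ancestral RUs A (40 bp) and B (39 bp).
name: SVA2
prefix: A
interior: random A B
interior_len_range: 6 14
suffix: B
mutation_rate: 0.01
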