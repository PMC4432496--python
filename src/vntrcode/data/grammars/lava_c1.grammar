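# LAVA_C1: N-type 53 bp RU at the second 5' position; a second structure
# lacking N is represented equally among the elements.  Unstructured interior.
name: LAVA_C1
prefix: A N B
alt_prefix: A B B
alt_prefix_frac: 0.5
interior: random B C D A
interior_len_range: 6 16
suffix: D C.T
mutation_rate: 0.005
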