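# Youngest human subfamily: the full ABCAAAB'CACAAF 5' array,
# internal K_nGC' expansions and the KGC'T 3' array.
name: SVA_F
prefix: A B C A A A B' C A C A A F
interior: motif K* G C'
interior_copy_range: 1 4
interior_repeats: 2 6
suffix: K G C' T
mutation_rate: 0.005
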