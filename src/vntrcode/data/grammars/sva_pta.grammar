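# Chimpanzee-specific subfamily derived from SVA_D: same K_nGC' arrays.
name: SVA_PtA
prefix: A B C A A A B' C A C A
interior: motif K* G C'
interior_copy_range: 1 4
interior_repeats: 2 6
suffix: K G C' T
mutation_rate: 0.005
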