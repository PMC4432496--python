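# Young human SVA subfamily: extended 5' array, internal K_nGC' expansions,
# KGC'T 3' array.  Prefix beyond ABCA is illustrative (7-14 RU range).
name: SVA_D
prefix: A B C A A A B' C A C A
interior: motif K* G C'
interior_copy_range: 1 4
interior_repeats: 2 6
suffix: K G C' T
mutation_rate: 0.005
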