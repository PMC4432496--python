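# vntrcode

Repeat-unit analysis of the central VNTR domain of composite
retrotransposons (SVA, LAVA, PVA, FVA).

## The problem

Hominoid genomes carry non-autonomous retrotransposons built around a
central **VNTR** (variable number of tandem repeats) domain: SVA in great
apes and humans, LAVA/PVA/FVA in gibbons. The domain was long treated as a
random pile of 30–50 bp GC-rich repeats, but its repeat units (RUs) in fact
fall into a small coded alphabet — ancestral units A (40 bp) and B (39 bp)
plus seventeen later types C–S and a terminal unit T, with prime/superscript
sequence variants (B′, C′, C^T …) — and the units are arranged in
subfamily-specific **arrays**: a conserved 5′ array that expands from ABCA
in SVA_A to ABCAAAB′CACAAF in SVA_F, internal expansion arrays such as
K<sub>n</sub>GC′ in the young SVA subfamilies, and the 3′ array KGC′T.
Between orthologous elements in different species the domain is remodelled
at the DNA level by indels whose breakpoints carry 5–42 bp of
**microhomology** — the signature of replication slippage or
microhomology-mediated repair, bounded by the ~34 bp minimal efficient
processing segment of NAHR and the ~200 bp reach (one Okazaki fragment) of
slippage.

`vntrcode` implements that entire analysis as a tested library for people
who study tandem-repeat evolution in mobile elements:

* **`ru_library`** — the coded RU alphabet: types, variants, curated
  derivation graph, structured-header FASTA I/O. The packaged consensus
  sequences are deterministic synthetic stand-ins that honour every
  published unit length (see `docs/methods.md`).
* **`segmentation`** — optimal decomposition of a VNTR sequence into an RU
  token string ("repeat schema") by a minimum-cost dynamic program
  (`D(j) = min_i D(i) + unitcost(i,j) + τ`, unit cost = Levenshtein distance
  to the closest library consensus, unclassified tokens at
  `⌈0.5·w⌉`), plus majority-rule de-novo unit discovery.
* **`array_analysis`** — conserved 5′/3′ arrays at a support threshold θ,
  position-specific nucleotide consensi, and run-length-compressed motif
  mining (K<sub>n</sub>GC′-style internal arrays).
* **`ortholog_compare`** — indel calling between orthologs (token-level
  edit script, then affine-gap realignment in windows), left-normalized
  breakpoints, exact and mismatch-tolerant microhomology, and mechanism
  compatibility labels (`precise_ru_indel`, `ru_conversion_microindel`,
  `mh_mediated`, `slippage_compatible`, `nahr_compatible`,
  `mmej_signature`).
* **`synthetic_data`** — grammar-driven element sets and ortholog pairs
  with planted, microhomology-designed indels, all with byte-exact ground
  truth.
* **`cli_pipeline`** — `vntrcode tokenize|discover|arrays|compare|simulate`.

The numbered scripts under `analysis/` walk through the study:
`01_build_library.py` (the alphabet), `02_simulate_subfamilies.py` (the
element sets), `03_decompose_and_arrays.py` (array structure per
subfamily), `04_ortholog_remodelling.py` (microhomology at remodelling
breakpoints). Tables land in `results/`.

## Worked example

```python
from vntrcode import (load_packaged_library, segment_vntr, VNTRElement,
                      make_pair, compare_pair)

lib = load_packaged_library()
seq = "".join(lib.consensus(c) for c in "ABCA")
print(segment_vntr(VNTRElement("toy", "SVA_A", seq), lib).code_string)
# A-B-C-A

# precise excision of the B unit between two orthologs
pair = make_pair("toy", VNTRElement("h1", "t", seq),
                 VNTRElement("h2", "t", seq.replace(lib.consensus("B"), "", 1)), lib)
ev = compare_pair(pair, lib)[0]
print(ev.start, ev.end, sorted(ev.labels))
# 39 78 ['precise_ru_indel', 'slippage_compatible']
```

The event spans 39 bp (one whole B unit; the left-normalized breakpoint
sits one base left of the token boundary, inside the indel's ambiguity
range) and is labelled a precise RU excision that is within the reach of
replication slippage.

Running `python analysis/03_decompose_and_arrays.py` prints, per simulated
subfamily, the derived structures, e.g.

```
subfamily  n         prefix  suffix top_motif motif_copies
    SVA_A 10           ABCA      AT         -            -
    SVA_F 10 ABCAAAB'CACAAF   KGC'T    K_nGC'          1-4
   LAVA_E 10           ANBB  OPC.TT         -            -
```

— the 5′ array expansion from ABCA to ABCAAAB′CACAAF, the K<sub>n</sub>GC′
interior with the KGC′T 3′ array, and short (≤ 5 RU) conserved LAVA ends.

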