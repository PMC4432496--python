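#!/usr/bin/env python
"""Generate the synthetic study material.

Draws ten elements from every packaged subfamily grammar (human SVA_A/D/F,
chimpanzee SVA_PtA, a young orangutan subfamily, gibbon LAVA_C1/E, and an
SVA2-like ancestral set) with the default point-mutation rate, and writes
each set as FASTA plus ground truth under results/sim/.
"""

from pathlib import Path

from vntrcode.ru_library import load_packaged_library
from vntrcode.synthetic_data import (
    generate_subfamily_set,
    load_packaged_grammar,
    packaged_grammar_names,
    write_elements_fasta,
    write_truth_jsonl,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1


def main():
    lib = load_packaged_library()
    OUT.mkdir(parents=True, exist_ok=True)
    for name in packaged_grammar_names():
        g = load_packaged_grammar(name)
        els, truths = generate_subfamily_set(g, 10, SEED, lib)
        write_elements_fasta(els, OUT / f"{name}.fasta")
        write_truth_jsonl(truths, OUT / f"{name}.truth.jsonl")
        lens = [len(e.sequence) for e in els]
        print(
            f"{g.name:10s} n=10  VNTR length {min(lens)}-{max(lens)} bp  "
            f"mutation rate {g.mutation_rate}"
        )
    print(f"\nWrote element sets and truth to {OUT}")


if __name__ == "__main__":
    main()
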