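#!/usr/bin/env python
"""Microhomology at the breakpoints of VNTR remodelling events.

Builds 100 orthologous pairs with one planted deletion each (lengths 37-150
bp, designed breakpoint homology 0-42 bp on a structureless background),
calls and classifies the events, and summarizes recovery, the measured
microhomology distribution and mechanism-compatibility labels.  Also runs
two anchored cases: precise excision of a whole repeat unit and the 3 bp
A->C repeat-unit conversion.  Writes results/events.tsv and
results/remodelling_summary.json.
"""

import json
from collections import Counter
from pathlib import Path

from vntrcode.ortholog_compare import compare_pair, events_to_frame, make_pair
from vntrcode.ru_library import load_packaged_library
from vntrcode.segmentation import VNTRElement
from vntrcode.synthetic_data import make_random_planted_pair

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main():
    lib = load_packaged_library()
    all_events, recovered, mh_values = [], 0, []
    labels = Counter()
    for k in range(100):
        e1, e2, truth = make_random_planted_pair(SEED * 1000 + k)
        pair = make_pair(f"pair{k:03d}", e1, e2, lib)
        events = compare_pair(pair, lib)
        all_events.extend(events)
        for ev in events:
            labels.update(ev.labels)
            mh_values.append(ev.mh_exact_right)
        if len(events) == 1 and [events[0].start, events[0].end] == truth["segment"]:
            recovered += 1

    base = [lib.consensus(c) for c in "ABCA"]
    precise = compare_pair(
        make_pair(
            "precise",
            VNTRElement("l", "t", "".join(base)),
            VNTRElement("s", "t", "".join(base[:1] + base[2:])),
            lib,
        ),
        lib,
    )
    conv = compare_pair(
        make_pair(
            "conversion",
            VNTRElement("l", "t", lib.consensus("B") + lib.consensus("A") + lib.consensus("K")),
            VNTRElement("s", "t", lib.consensus("B") + lib.consensus("C") + lib.consensus("K")),
            lib,
        ),
        lib,
    )
    all_events.extend(precise + conv)

    (ROOT / "results").mkdir(exist_ok=True)
    events_to_frame(all_events).to_csv(ROOT / "results" / "events.tsv", sep="\t", index=False)
    summary = {
        "n_pairs": 100,
        "planted_recovered": recovered,
        "mh_exact_range_bp": [min(mh_values), max(mh_values)],
        "label_counts": dict(sorted(labels.items())),
        "whole_ru_excision_labels": sorted(precise[0].labels) if precise else [],
        "conversion_labels": sorted(conv[0].labels) if conv else [],
        "conversion_tokens": conv[0].converted_tokens if conv else [],
    }
    (ROOT / "results" / "remodelling_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(json.dumps(summary, indent=2))
    print(
        f"\nRecovered {recovered}/100 planted events at their exact normalized "
        f"breakpoints;\nmeasured exact microhomologies span "
        f"{min(mh_values)}-{max(mh_values)} bp."
    )
    print(f"Wrote {ROOT / 'results' / 'events.tsv'}")


if __name__ == "__main__":
    main()
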