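#!/usr/bin/env python
"""Survey the packaged repeat-unit alphabet.

Loads the packaged (synthetic-consensus) RU library, tabulates every type
with its length, family scope and curated parents, and reports the roots of
the derivation graph.  Writes results/ru_library_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from vntrcode.ru_library import derivation_graph, graph_roots, load_packaged_library

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    lib = load_packaged_library()
    rows = []
    for code, u in sorted(lib.units.items()):
        rows.append(
            {
                "code": code,
                "length_bp": u.length,
                "family_scope": u.family_scope,
                "parents": ",".join(u.parents) or "-",
                "terminal": u.terminal,
                "underived": u.underived,
                "n_variants": len(lib.variants_of(code)),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "ru_library_summary.tsv", sep="\t", index=False)

    g = derivation_graph(lib)
    print(df.to_string(index=False))
    print(f"\n{len(lib.units)} repeat-unit types, {len(lib.variants)} variants.")
    print(f"Derivation roots (ancestral units): {graph_roots(g)}")
    print("S is flagged derivation-undetermined (chimpanzee-specific).")
    print(f"Wrote {OUT / 'ru_library_summary.tsv'}")


if __name__ == "__main__":
    main()
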