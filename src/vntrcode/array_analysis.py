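"""Subfamily-level structure of VNTR repeat schemata.

Given the repeat schemata of the elements of one subfamily, derive

* the conserved 5' and 3' arrays — the longest token prefixes/suffixes shared
  (at a support threshold) across elements, e.g. the ABCA array common to all
  human SVA subfamilies, expanding to ABCAAAB'CACAAF in SVA_F, or the KGC'T
  3' array of SVA_D-F;
* position-specific nucleotide consensi for the repeat units occupying a
  conserved array slot;
* repeated internal arrays — run-length-compressed motifs such as the
  K_nGC' expansions in the central part of SVA_D-F VNTRs or the Q/C_n
  scaffolds of young orangutan subfamilies.

Support for "conserved" is a parameter (default 0.7): the source material
never states whether its consensus arrays demanded unanimity or a majority
across the sampled elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .segmentation import RepeatSchema, VNTRElement, render_label

__all__ = [
    "ArrayConsensus",
    "Motif",
    "ArrayAnalysisError",
    "consensus_arrays",
    "position_specific_consensus",
    "mine_internal_arrays",
]

Key = tuple[str, str]


class ArrayAnalysisError(ValueError):
    pass


@dataclass
class Motif:
    """A repeated internal array with at most one run-variable position."""

    unit_tokens: list[Key]
    variable_pos: int | None
    copy_range: tuple[int, int]
    occurrences: int
    n_elements: int

    def render(self) -> str:
        parts = []
        for p, (code, tag) in enumerate(self.unit_tokens):
            lab = render_label(code, tag)
            if p == self.variable_pos:
                lab += "_n"
            parts.append(lab)
        return "".join(parts)


@dataclass
class ArrayConsensus:
    subfamily: str
    prefix: list[tuple[str, str, float]]  # (code, tag, support fraction)
    suffix: list[tuple[str, str, float]]
    internal_motifs: list[Motif] = field(default_factory=list)
    alt_prefixes: list[tuple[list[Key], float]] = field(default_factory=list)
    n_elements: int = 0
    support_threshold: float = 0.7
    variant_sensitive: bool = True

    @property
    def prefix_keys(self) -> list[Key]:
        return [(c, t) for c, t, _ in self.prefix]

    @property
    def suffix_keys(self) -> list[Key]:
        return [(c, t) for c, t, _ in self.suffix]

    def render_prefix(self) -> str:
        return "".join(render_label(c, t) for c, t, _ in self.prefix)

    def render_suffix(self) -> str:
        return "".join(render_label(c, t) for c, t, _ in self.suffix)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subfamily": self.subfamily,
                "n_elements": self.n_elements,
                "support_threshold": self.support_threshold,
                "prefix": [
                    {"code": c, "tag": t, "support": s} for c, t, s in self.prefix
                ],
                "suffix": [
                    {"code": c, "tag": t, "support": s} for c, t, s in self.suffix
                ],
                "alt_prefix": [
                    {"tokens": [list(k) for k in toks], "support": s}
                    for toks, s in self.alt_prefixes
                ],
                "motifs": [
                    {
                        "tokens": [list(k) for k in m.unit_tokens],
                        "variable_pos": m.variable_pos,
                        "copy_range": list(m.copy_range),
                        "occurrences": m.occurrences,
                        "n_elements": m.n_elements,
                        "render": m.render(),
                    }
                    for m in self.internal_motifs
                ],
            },
            indent=2,
        )


def _schema_keys(s: RepeatSchema, variant_sensitive: bool) -> list[Key]:
    if variant_sensitive:
        return s.keys
    return [(c, "") for c, _ in s.keys]


def _check_input(schemata: list[RepeatSchema]) -> str:
    if not schemata:
        raise ArrayAnalysisError("no schemata given")
    labels = {s.subfamily for s in schemata}
    if len(labels) > 1:
        raise ArrayAnalysisError(f"mixed subfamily labels: {sorted(labels)}")
    return labels.pop()


def _derive_prefix(
    key_lists: list[list[Key]], theta: float, n_total: int
) -> list[tuple[Key, float]]:
    """Greedy maximal prefix: extend while the best next token keeps the
    fraction of schemata starting with the whole prefix at or above theta."""
    prefix: list[tuple[Key, float]] = []
    live = list(range(len(key_lists)))
    k = 0
    while True:
        counts: dict[Key, int] = {}
        for i in live:
            if len(key_lists[i]) > k:
                t = key_lists[i][k]
                counts[t] = counts.get(t, 0) + 1
        if not counts:
            break
        best = min(counts, key=lambda t: (-counts[t], t))
        support = counts[best] / n_total
        if support < theta:
            break
        prefix.append((best, support))
        live = [i for i in live if len(key_lists[i]) > k and key_lists[i][k] == best]
        k += 1
    return prefix


def consensus_arrays(
    schemata: list[RepeatSchema],
    theta: float = 0.7,
    variant_sensitive: bool = True,
    alt_min: float = 0.2,
) -> ArrayConsensus:
    """Derive the conserved 5' and 3' arrays of one subfamily.

    The prefix is the longest token list P such that the fraction of
    schemata starting with P stays >= theta; support is reported per token.
    The suffix is derived symmetrically from the 3' end.  Where a second 5'
    structure coexists (minority fractions of at least ``alt_min``), the best
    alternative continuation is reported as well instead of being forced
    into the consensus.
    """
    if len(schemata) < 2:
        raise ArrayAnalysisError("need at least two schemata")
    subfamily = _check_input(schemata)
    if not 0 < theta <= 1:
        raise ArrayAnalysisError("theta must be in (0, 1]")
    ordered = sorted(schemata, key=lambda s: s.element_id)
    keys = [_schema_keys(s, variant_sensitive) for s in ordered]
    n = len(keys)

    pre = _derive_prefix(keys, theta, n)
    suf = _derive_prefix([list(reversed(kl)) for kl in keys], theta, n)
    suf.reverse()

    # alternative 5' structures among schemata diverging at the stop position
    alt: list[tuple[list[Key], float]] = []
    k = len(pre)
    matching = [kl for kl in keys if kl[:k] == [t for t, _ in pre]]
    counts: dict[Key, int] = {}
    for kl in matching:
        if len(kl) > k:
            t = kl[k]
            counts[t] = counts.get(t, 0) + 1
    for t in sorted(counts, key=lambda t: (-counts[t], t))[:2]:
        frac = counts[t] / n
        if frac < alt_min or frac >= theta:
            continue
        subset = [kl[k:] for kl in matching if len(kl) > k and kl[k] == t]
        ext = _derive_prefix(subset, theta, len(subset))
        alt.append(([t for t, _ in pre] + [tt for tt, _ in ext], frac))

    return ArrayConsensus(
        subfamily=subfamily,
        prefix=[(c, t, round(s, 4)) for (c, t), s in pre],
        suffix=[(c, t, round(s, 4)) for (c, t), s in suf],
        alt_prefixes=alt,
        n_elements=n,
        support_threshold=theta,
        variant_sensitive=variant_sensitive,
    )


def position_specific_consensus(
    schemata: list[RepeatSchema],
    elements: list[VNTRElement],
    position: int,
    theta: float = 0.7,
    which: str = "prefix",
    variant_sensitive: bool = True,
) -> str:
    """Majority-rule nucleotide consensus of the RU at one conserved slot.

    ``position`` indexes into the derived prefix (``which="prefix"``) or
    suffix (``which="suffix"``, 0 = leftmost suffix token).  Elements whose
    schema does not carry the conserved array at that slot do not
    contribute; if more than half are in that situation the position is
    rejected.
    """
    _check_input(schemata)
    arr = consensus_arrays(schemata, theta=theta, variant_sensitive=variant_sensitive)
    conserved = arr.prefix_keys if which == "prefix" else arr.suffix_keys
    if not 0 <= position < len(conserved):
        raise ArrayAnalysisError(
            f"position {position} outside the derived {which} "
            f"(length {len(conserved)})"
        )
    seqs = {e.id: e.sequence for e in elements}
    subs: list[str] = []
    for s in schemata:
        kl = _schema_keys(s, variant_sensitive)
        if which == "prefix":
            ok = kl[: position + 1] == conserved[: position + 1]
            tok = s.tokens[position] if ok and len(s.tokens) > position else None
        else:
            m = len(conserved) - position  # tokens from the 3' end
            ok = len(kl) >= m and kl[-m:] == conserved[position:]
            tok = s.tokens[-m] if ok else None
        if tok is None or s.element_id not in seqs:
            continue
        subs.append(seqs[s.element_id][tok.start : tok.end])
    if len(subs) * 2 < len(schemata):
        raise ArrayAnalysisError(
            f"{which} position {position} is outside the conserved array "
            f"for more than half of the elements"
        )
    lengths = [len(x) for x in subs]
    modal = min(sorted(set(lengths)), key=lambda L: (-lengths.count(L), L))
    from .segmentation import _majority_consensus

    cons, _ties = _majority_consensus([x for x in subs if len(x) == modal])
    return cons


# ----------------------------------------------------------------------
# Internal array mining
# ----------------------------------------------------------------------

def _compress(kl: list[Key]) -> list[tuple[Key, int]]:
    out: list[tuple[Key, int]] = []
    for t in kl:
        if out and out[-1][0] == t:
            out[-1] = (t, out[-1][1] + 1)
        else:
            out.append((t, 1))
    return out


def _occurrences(comp: list[tuple[Key, int]], pat: tuple[Key, ...]):
    """Greedy non-overlapping matches of a symbol pattern; count vectors."""
    hits = []
    i = 0
    m = len(pat)
    while i + m <= len(comp):
        if tuple(sym for sym, _ in comp[i : i + m]) == pat:
            hits.append(tuple(c for _, c in comp[i : i + m]))
            i += m
        else:
            i += 1
    return hits


def _is_cyclic_subseq(small: tuple, big: tuple) -> bool:
    doubled = big + big
    for i in range(len(big)):
        if doubled[i : i + len(small)] == small:
            return True
    return False


def mine_internal_arrays(
    schemata: list[RepeatSchema],
    theta: float = 0.7,
    max_motif_len: int = 6,
    variant_sensitive: bool = True,
) -> list[Motif]:
    """Mine repeated internal arrays from the schemata of one subfamily.

    Token strings are run-length compressed; repeated compressed
    subsequences of 2 to ``max_motif_len`` symbols with at most one
    run-variable position are reported when they occur at least twice in at
    least ``theta`` of the elements.  The whole schema is scanned rather
    than only the strict interior: the greedy conserved-array derivation
    absorbs the constant leading edge of an expansion array, so restricting
    the scan to the region between derived prefix and suffix would starve
    exactly the motifs of interest; single-occurrence structure (such as a
    conserved prefix itself) is rejected by the twice-per-element rule.
    Among cyclic rotations of one pattern only the most frequent (then
    lexicographically smallest) is kept, and shorter patterns fully
    contained in a reported longer one with at least as many occurrences
    are suppressed.
    """
    _check_input(schemata)
    interiors: list[list[tuple[Key, int]]] = []
    for s in sorted(schemata, key=lambda x: x.element_id):
        interiors.append(_compress(_schema_keys(s, variant_sensitive)))
    n_el = len(interiors)

    candidates: set[tuple[Key, ...]] = set()
    for comp in interiors:
        syms = [sym for sym, _ in comp]
        for m in range(2, max_motif_len + 1):
            for i in range(len(syms) - m + 1):
                candidates.add(tuple(syms[i : i + m]))

    motifs: list[Motif] = []
    for pat in sorted(candidates):
        per_el = [_occurrences(comp, pat) for comp in interiors]
        total = sum(len(h) for h in per_el)
        if total < 2:
            continue
        frac = sum(1 for h in per_el if len(h) >= 2) / n_el
        if frac < theta:
            continue
        counts = np.array([h for hits in per_el for h in hits])
        ranges = counts.max(axis=0) - counts.min(axis=0)
        varying = np.nonzero(ranges > 0)[0]
        if len(varying) > 1:
            continue
        if len(varying) == 1:
            vp = int(varying[0])
        else:
            maxima = counts.max(axis=0)
            vp = int(np.argmax(maxima)) if maxima.max() > 1 else None
        lo, hi = (
            (int(counts[:, vp].min()), int(counts[:, vp].max()))
            if vp is not None
            else (1, 1)
        )
        motifs.append(
            Motif(
                unit_tokens=list(pat),
                variable_pos=vp,
                copy_range=(lo, hi),
                occurrences=total,
                n_elements=sum(1 for h in per_el if h),
            )
        )

    # Motifs are ranked by coverage (occurrences x token length): a true
    # 3-symbol expansion array scores above both its 2-symbol sub-patterns
    # and longer patterns spanning two of its instances.
    def _score(m: Motif) -> int:
        return m.occurrences * len(m.unit_tokens)

    # rotation dedup: keep the most frequent rotation of each pattern class
    kept: list[Motif] = []
    for m in sorted(motifs, key=lambda m: (-m.occurrences, tuple(m.unit_tokens))):
        if any(
            len(o.unit_tokens) == len(m.unit_tokens)
            and _is_cyclic_subseq(tuple(m.unit_tokens), tuple(o.unit_tokens))
            for o in kept
        ):
            continue
        kept.append(m)
    # containment: drop a pattern when a cyclically containing/contained
    # pattern of different length carries at least as much coverage
    final = [
        m
        for m in kept
        if not any(
            (
                len(o.unit_tokens) > len(m.unit_tokens)
                and _score(o) >= _score(m)
                and _is_cyclic_subseq(tuple(m.unit_tokens), tuple(o.unit_tokens))
            )
            or (
                len(o.unit_tokens) < len(m.unit_tokens)
                and _score(o) > _score(m)
                and _is_cyclic_subseq(tuple(o.unit_tokens), tuple(m.unit_tokens))
            )
            for o in kept
        )
    ]
    final.sort(key=lambda m: (-_score(m), -len(m.unit_tokens), tuple(m.unit_tokens)))
    return final


# ----------------------------------------------------------------------
# Diagnostic (core) arrays
# ----------------------------------------------------------------------

def _matches_motif_head(tokens: list[Key], motif: Motif) -> int:
    """If tokens begin with one complete motif instance, return its token
    length (variable run of any length >= 1); else 0."""
    pos = 0
    for p, sym in enumerate(motif.unit_tokens):
        if pos >= len(tokens) or tokens[pos] != sym:
            return 0
        pos += 1
        if p == motif.variable_pos:
            while pos < len(tokens) and tokens[pos] == sym:
                pos += 1
    return pos


def core_arrays(
    arr: ArrayConsensus, motifs: list[Motif]
) -> tuple[list[Key], list[Key]]:
    """Trim a derived conserved array down to its diagnostic core.

    A support-threshold prefix extends into the constant leading edge of an
    internal expansion array (every element starts its K_nGC' region with at
    least one K), so the derived 5' array is trimmed of trailing tokens that
    belong to the top internal motif.  The derived 3' array keeps exactly one
    complete motif instance ahead of its non-motif tail (the subfamily 3'
    arrays of the source material are written that way: KGC'T is one KGC'
    copy plus the terminal unit).
    """
    prefix = list(arr.prefix_keys)
    suffix = list(arr.suffix_keys)
    if not motifs:
        return prefix, suffix
    top = motifs[0]
    motif_set = set(top.unit_tokens)
    while prefix and prefix[-1] in motif_set:
        prefix.pop()
    # drop whole leading motif instances while a complete one still follows
    while True:
        head = _matches_motif_head(suffix, top)
        if head and _matches_motif_head(suffix[head:], top):
            suffix = suffix[head:]
        else:
            break
    # collapse a surplus leading run at the motif's variable position
    if top.variable_pos == 0 and _matches_motif_head(suffix, top):
        while len(suffix) > 1 and suffix[0] == suffix[1]:
            suffix = suffix[1:]
    return prefix, suffix
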