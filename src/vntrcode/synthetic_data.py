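"""Synthetic study material with recorded ground truth.

Everything the upstream stages consume can be generated here with full
ground truth: the repeat-unit library itself, subfamily element sets drawn
from array grammars, and orthologous pairs carrying planted indels with
designed breakpoint microhomologies.

The packaged repeat-unit library is *synthetic*: real RU consensus
sequences exist only in figure panels that are not machine-readable, so
:func:`build_ru_library` generates a deterministic GC-rich stand-in that
honours every repeat-unit length stated in the text (A 40 bp, B 39 bp,
D 40, E 41, G 41, H 42, I 47, K 49, N 53, O 42, P 42, Q 43, R 38), the
derivation constraints (A and B ancestral roots, S underivable, C obtained
from A by a 3 bp deletion so that the documented 3 bp A<->C repeat-unit
conversion is reproducible), and separation constraints that make the
types unambiguous to classify (same-length types differ by >= 8
substitutions; variants sit within 3 edits of their base type).

Element generation emulates the study's sample sets: 5-20 elements per
subfamily, drawn from a grammar of conserved 5' prefix, interior (either a
run-variable repeated motif, as in SVA_D-F K_nGC' arrays, or an
unstructured token pool, as in LAVA interiors) and conserved 3' suffix,
with uniform point substitutions.  Mutation replay is byte-exact and
recorded in :class:`SimTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files

import edlib
import numpy as np

from .ru_library import (
    LibraryError,
    RepeatUnitType,
    RepeatUnitVariant,
    RULibrary,
    write_library,
)
from .segmentation import VNTRElement

__all__ = [
    "build_ru_library",
    "SubfamilyGrammar",
    "SimTruth",
    "PlantedEvent",
    "parse_grammar",
    "load_packaged_grammar",
    "packaged_grammar_names",
    "generate_subfamily_set",
    "make_ortholog_pair",
    "plant_deletion",
    "random_element",
    "make_random_planted_pair",
    "write_elements_fasta",
    "read_elements_fasta",
]

_BASES = "ACGT"
# GC-rich composition of VNTR repeat units
_BASE_P = np.array([0.15, 0.35, 0.35, 0.15])

_PRINTED_LENGTHS = {
    "A": 40, "B": 39, "D": 40, "E": 41, "G": 41, "H": 42, "I": 47,
    "K": 49, "N": 53, "O": 42, "P": 42, "Q": 43, "R": 38,
}
# lengths not printed anywhere; package choices (see docs/methods.md)
_CHOSEN_LENGTHS = {"C": 37, "F": 48, "J": 44, "L": 50, "M": 45, "S": 41, "T": 36}

RU_LENGTHS = {**_PRINTED_LENGTHS, **_CHOSEN_LENGTHS}


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=_BASE_P))


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        choices = [b for b in _BASES if b != s[pos]]
        s[pos] = choices[rng.integers(3)]
    return "".join(s)


def _resize(rng: np.random.Generator, seq: str, target_len: int) -> str:
    s = list(seq)
    while len(s) > target_len:
        del s[rng.integers(len(s))]
    while len(s) < target_len:
        pos = rng.integers(len(s) + 1)
        s.insert(pos, _BASES[rng.choice(4, p=_BASE_P)])
    return "".join(s)


def _derive(rng, parent: str, target_len: int, n_subs: int) -> str:
    return _substitute(rng, _resize(rng, parent, target_len), n_subs)


def _dist(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


# (code, parent, n_subs, family_scope, extras)
_TYPE_PLAN = [
    ("C", "A", 0, "shared", {}),       # A with a 3 bp deletion, no substitutions
    ("D", "A", 10, "LAVA", {}),
    ("E", "B", 8, "SVA", {}),
    ("G", "B", 9, "SVA", {}),
    ("H", "A", 8, "SVA", {}),
    ("I", "H", 8, "SVA", {}),
    ("F", "I", 8, "SVA", {}),
    ("K", "I", 9, "SVA", {}),
    ("L", "K", 8, "SVA", {}),
    ("J", "A", 8, "SVA", {"note": "figure-only"}),
    ("M", "B", 8, "LAVA", {"note": "figure-only"}),
    ("N", "D", 10, "LAVA", {}),
    ("O", "B", 9, "LAVA", {}),
    ("P", "O", 10, "LAVA", {}),
    ("Q", "B", 10, "orangutan_SVA", {}),
    ("R", "B", 9, "orangutan_SVA", {}),
    ("S", "", 0, "chimp_SVA",
     {"underived": True, "note": "derivation-undetermined"}),
    ("T", "C", 6, "SVA", {"terminal": True}),
]

# (base, tag, n_subs, scope_note)
_VARIANT_PLAN = [
    ("A", "5'", 2, "LAVA 5'-terminal A differs from internal A"),
    ("B", "'", 2, "second B-type repeat, SVA_B-F 5' arrays"),
    ("B", "5'", 3, "5'-most B-type RU, orangutan SVA / LAVA_B2"),
    ("B", "CCA", 3, "subfamily-specific internal B, LAVA_B2C"),
    ("C", "'", 2, "short C of the SVA_D-F internal/3' KGC' arrays"),
    ("C", "''", 3, "alternative short C, SVA_E LL'GC'/C'' arrays"),
    ("C", "T", 2, "sub-terminal C variant, LAVA_B1A onwards"),
    ("C", "TT", 3, "second sub-terminal C variant, LAVA_C1 to C4/D"),
    ("C", "5'", 2, "5'-terminal C, LAVA_B2B"),
    ("C", "C2", 3, "LAVA_C2-specific C"),
    ("D", "C2", 2, "LAVA_C2-specific D"),
    ("K", "'", 2, "5'-most K of internal K_nGC' arrays"),
    ("L", "'", 2, "second L of SVA_E LL'GC' arrays"),
]


def build_ru_library(seed: int = 20150516) -> RULibrary:
    """Deterministically build the packaged synthetic repeat-unit library.

    Retries derivation with fresh draws until the separation constraints
    hold: distinct types at least 3 edits apart (C sits exactly 3 from A,
    by the designed deletion), same-length types at least 8 apart, variants
    of one type mutually distinct.
    """
    rng = np.random.default_rng(seed)
    for _attempt in range(200):
        units: dict[str, str] = {}
        units["A"] = _rand_seq(rng, RU_LENGTHS["A"])
        units["B"] = _rand_seq(rng, RU_LENGTHS["B"])
        if _dist(units["A"], units["B"]) < 12:
            continue
        # C: pure 3 bp deletion from A at a fixed internal position
        a = units["A"]
        units["C"] = a[:18] + a[21:]
        ok = True
        for code, parent, n_subs, _scope, _extras in _TYPE_PLAN:
            if code == "C":
                continue
            src = units[parent] if parent else _rand_seq(rng, RU_LENGTHS[code])
            units[code] = _derive(rng, src, RU_LENGTHS[code], n_subs)
        # separation constraints between base types
        codes = sorted(units)
        for i, c1 in enumerate(codes):
            for c2 in codes[i + 1 :]:
                d = _dist(units[c1], units[c2])
                if {c1, c2} == {"A", "C"}:
                    if d != 3:
                        ok = False
                elif len(units[c1]) == len(units[c2]):
                    if d < 8:
                        ok = False
                elif d < 3:
                    ok = False
        if not ok:
            continue
        variants: dict[tuple[str, str], str] = {}
        for base, tag, n_subs, _note in _VARIANT_PLAN:
            variants[(base, tag)] = _substitute(rng, units[base], n_subs)
        by_base: dict[str, list[str]] = {}
        for (base, _tag), seq in variants.items():
            by_base.setdefault(base, []).append(seq)
        for base, seqs in by_base.items():
            pool = [units[base]] + seqs
            for i, s1 in enumerate(pool):
                for s2 in pool[i + 1 :]:
                    if _dist(s1, s2) < 2:
                        ok = False
        if not ok:
            continue

        lib = RULibrary(name="synthetic", provenance=(
            "Synthetic stand-in consensus sequences generated by "
            f"vntrcode.synthetic_data.build_ru_library(seed={seed}); "
            "printed repeat-unit lengths and derivation constraints honoured."
        ))
        lib.units["A"] = RepeatUnitType("A", units["A"], "shared", ())
        lib.units["B"] = RepeatUnitType("B", units["B"], "shared", ())
        for code, parent, _n, scope, extras in _TYPE_PLAN:
            lib.units[code] = RepeatUnitType(
                code=code,
                consensus=units[code],
                family_scope=scope,
                parents=(parent,) if parent else (),
                terminal=extras.get("terminal", False),
                underived=extras.get("underived", False),
                note=extras.get("note", ""),
            )
        for base, tag, _n, note in _VARIANT_PLAN:
            lib.variants[(base, tag)] = RepeatUnitVariant(
                base_code=base, tag=tag, consensus=variants[(base, tag)],
                scope_note=note,
            )
        return lib.validate()
    raise LibraryError("could not satisfy library separation constraints")


def write_packaged_library(path) -> None:
    write_library(build_ru_library(), path)


# ----------------------------------------------------------------------
# Grammars
# ----------------------------------------------------------------------

@dataclass
class SubfamilyGrammar:
    """Generating grammar for one subfamily's VNTR structure."""

    name: str
    prefix: list[tuple[str, str]]
    suffix: list[tuple[str, str]]
    interior_mode: str = "none"  # none | motif | random
    motif_tokens: list[tuple[str, str]] = field(default_factory=list)
    motif_variable_pos: int | None = None
    motif_copy_range: tuple[int, int] = (1, 1)
    motif_repeat_range: tuple[int, int] = (1, 1)
    random_pool: list[tuple[str, str]] = field(default_factory=list)
    random_len_range: tuple[int, int] = (0, 0)
    mutation_rate: float = 0.005
    indel_rate: float = 0.0
    alt_prefix: list[tuple[str, str]] | None = None
    alt_prefix_frac: float = 0.0

    def validate(self, lib: RULibrary) -> "SubfamilyGrammar":
        if not 0 <= self.mutation_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError(f"grammar {self.name}: rates must be in [0, 1]")
        referenced = list(self.prefix) + list(self.suffix) + list(self.motif_tokens) \
            + list(self.random_pool) + list(self.alt_prefix or [])
        for code, tag in referenced:
            try:
                lib.consensus(code, tag)
            except KeyError:
                raise ValueError(
                    f"grammar {self.name}: unknown repeat unit {code!r} tag {tag!r}"
                ) from None
        return self


def _parse_token_list(text: str) -> list[tuple[str, str]]:
    from .segmentation import decode_code_string

    toks = text.split()
    return decode_code_string("-".join(toks)) if toks else []


def parse_grammar(text: str) -> SubfamilyGrammar:
    """Parse the key-value grammar dialect (one `key: value` per line)."""
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition(":")
        kv[k.strip()] = v.strip()
    g = SubfamilyGrammar(
        name=kv.get("name", "?"),
        prefix=_parse_token_list(kv.get("prefix", "")),
        suffix=_parse_token_list(kv.get("suffix", "")),
        mutation_rate=float(kv.get("mutation_rate", 0.005)),
        indel_rate=float(kv.get("indel_rate", 0.0)),
    )
    interior = kv.get("interior", "")
    if interior.startswith("motif"):
        g.interior_mode = "motif"
        toks = interior.split()[1:]
        var = [i for i, t in enumerate(toks) if t.endswith("*")]
        g.motif_variable_pos = var[0] if var else None
        g.motif_tokens = _parse_token_list(" ".join(t.rstrip("*") for t in toks))
        if "interior_copy_range" in kv:
            lo, hi = kv["interior_copy_range"].split()
            g.motif_copy_range = (int(lo), int(hi))
        if "interior_repeats" in kv:
            lo, hi = kv["interior_repeats"].split()
            g.motif_repeat_range = (int(lo), int(hi))
    elif interior.startswith("random"):
        g.interior_mode = "random"
        g.random_pool = _parse_token_list(" ".join(interior.split()[1:]))
        if "interior_len_range" in kv:
            lo, hi = kv["interior_len_range"].split()
            g.random_len_range = (int(lo), int(hi))
    if "alt_prefix" in kv:
        g.alt_prefix = _parse_token_list(kv["alt_prefix"])
        g.alt_prefix_frac = float(kv.get("alt_prefix_frac", 0.0))
    return g


def packaged_grammar_names() -> list[str]:
    root = files("vntrcode") / "data" / "grammars"
    return sorted(p.name[: -len(".grammar")] for p in root.iterdir()
                  if p.name.endswith(".grammar"))


def load_packaged_grammar(name: str) -> SubfamilyGrammar:
    path = files("vntrcode") / "data" / "grammars" / f"{name}.grammar"
    return parse_grammar(path.read_text())


# ----------------------------------------------------------------------
# Element generation
# ----------------------------------------------------------------------

@dataclass
class SimTruth:
    element_id: str
    generating_tokens: list[tuple[str, str]]
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    token_indels: list[tuple[str, int]] = field(default_factory=list)
    planted_events: list[dict] = field(default_factory=list)

    def clean_sequence(self, lib: RULibrary) -> str:
        return "".join(lib.consensus(c, t) for c, t in self.generating_tokens)

    def replay(self, lib: RULibrary) -> str:
        """Re-derive the emitted sequence from tokens + mutations (byte-exact)."""
        s = list(self.clean_sequence(lib))
        for pos, old, new in self.mutations:
            assert s[pos] == old
            s[pos] = new
        return "".join(s)

    def token_bounds(self, lib: RULibrary) -> list[tuple[int, int]]:
        bounds, pos = [], 0
        for c, t in self.generating_tokens:
            L = len(lib.consensus(c, t))
            bounds.append((pos, pos + L))
            pos += L
        return bounds


def _expand_tokens(g: SubfamilyGrammar, rng: np.random.Generator) -> list[tuple[str, str]]:
    if g.alt_prefix is not None and rng.random() < g.alt_prefix_frac:
        toks = list(g.alt_prefix)
    else:
        toks = list(g.prefix)
    if g.interior_mode == "motif":
        lo, hi = g.motif_repeat_range
        for _ in range(int(rng.integers(lo, hi + 1))):
            for p, t in enumerate(g.motif_tokens):
                reps = 1
                if p == g.motif_variable_pos:
                    clo, chi = g.motif_copy_range
                    reps = int(rng.integers(clo, chi + 1))
                toks.extend([t] * reps)
    elif g.interior_mode == "random":
        lo, hi = g.random_len_range
        n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        for _ in range(n):
            toks.append(g.random_pool[rng.integers(len(g.random_pool))])
    toks.extend(g.suffix)
    return toks


def generate_subfamily_set(
    grammar: SubfamilyGrammar,
    n: int,
    seed: int,
    lib: RULibrary,
) -> tuple[list[VNTRElement], list[SimTruth]]:
    """Generate n elements of one subfamily with recorded ground truth."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grammar.validate(lib)
    rng = np.random.default_rng(seed)
    elements, truths = [], []
    for k in range(n):
        toks = _expand_tokens(grammar, rng)
        if grammar.indel_rate and rng.random() < grammar.indel_rate and len(toks) > 1:
            idx = int(rng.integers(len(toks)))
            if rng.random() < 0.5:
                toks = toks[:idx] + [toks[idx]] + toks[idx:]
                indel = ("duplication", idx)
            else:
                toks = toks[:idx] + toks[idx + 1 :]
                indel = ("deletion", idx)
            token_indels = [indel]
        else:
            token_indels = []
        truth = SimTruth(
            element_id=f"{grammar.name}_{k:03d}",
            generating_tokens=toks,
            token_indels=token_indels,
        )
        s = list(truth.clean_sequence(lib))
        hit = np.nonzero(rng.random(len(s)) < grammar.mutation_rate)[0]
        for pos in hit:
            old = s[pos]
            new = [b for b in _BASES if b != old][rng.integers(3)]
            truth.mutations.append((int(pos), old, new))
            s[pos] = new
        elements.append(
            VNTRElement(
                id=truth.element_id, subfamily=grammar.name, sequence="".join(s)
            )
        )
        truths.append(truth)
    return elements, truths


# ----------------------------------------------------------------------
# Ortholog pairs with planted events
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """Specification of one event to plant between the two haplotypes.

    ``span`` is a token index range (i, j) over the element's generating
    tokens unless ``bp_span`` gives explicit nucleotide coordinates.
    """

    span: tuple[int, int] | None = None
    bp_span: tuple[int, int] | None = None
    designed_mh: int = 0
    mismatch_positions: tuple[int, ...] = ()
    kind: str = "deletion"  # deletion | duplication


def plant_deletion(
    seq: str,
    start: int,
    end: int,
    mh: int,
    rng: np.random.Generator,
    mismatch_positions: tuple[int, ...] = (),
):
    """Plant a deletion of seq[start:end] with a designed breakpoint homology.

    The first ``mh`` bases of the deleted span are copied onto the right
    flank of the *ancestral* haplotype before deleting, which makes the
    planted homology the maximal exact one; ``mismatch_positions`` (0-based
    within the homology) degrade single bases of the copied tract, modelling
    post-event divergence.  Flank bases adjacent to the breakpoints are
    adjusted so the planted representation is already left-normalized and
    the homology does not extend by accident.  Returns (hap_long, hap_short,
    normalized_span).
    """
    if not 0 <= start < end <= len(seq):
        raise ValueError("invalid span")
    if mh > end - start:
        raise ValueError("designed homology longer than the span")
    s = list(seq)

    def _other(b):
        return _BASES[(_BASES.index(b) + 1 + rng.integers(3)) % 4]

    if mh > 0:
        for k in range(mh):
            if end + k < len(s):
                s[end + k] = s[start + k]
        for p in mismatch_positions:
            if p < mh and end + p < len(s):
                s[end + p] = _other(s[start + p])
    # stop accidental extension of the homology
    if end + mh < len(s) and s[end + mh] == s[start + mh]:
        s[end + mh] = _other(s[end + mh])
    # ensure the span is already left-normalized (flank base != last span base)
    if start > 0 and mh < end - start and s[start - 1] == s[end - 1]:
        s[end - 1] = _other(s[end - 1])
    hap_long = "".join(s)
    hap_short = hap_long[:start] + hap_long[end:]
    return hap_long, hap_short, (start, end)


def make_ortholog_pair(
    element: VNTRElement,
    events: list[PlantedEvent],
    seed: int,
    lib: RULibrary | None = None,
    truth: SimTruth | None = None,
) -> tuple[VNTRElement, VNTRElement, list[dict]]:
    """Derive an orthologous pair from one element by planting events.

    Returns the two haplotype elements (``*_h1`` keeps every planted
    segment, ``*_h2`` lacks the deletions / carries the duplications) and
    the ground-truth event records with normalized coordinates on the
    longer haplotype.  Spans must not overlap.
    """
    rng = np.random.default_rng(seed)
    spans = []
    for ev in events:
        if ev.bp_span is not None:
            spans.append((ev.bp_span, ev))
        else:
            if truth is None or lib is None:
                raise ValueError("token spans require the element's truth and library")
            bounds = truth.token_bounds(lib)
            i, j = ev.span
            if not 0 <= i < j <= len(bounds):
                raise ValueError(f"token span {ev.span} out of range")
            spans.append(((bounds[i][0], bounds[j - 1][1]), ev))
    spans.sort(key=lambda x: x[0])
    for ((s1, e1), ev1), ((s2, _e2), _ev2) in zip(spans, spans[1:]):
        if s2 < e1 + ev1.designed_mh:
            raise ValueError(
                "planted spans overlap (spans must be separated by at least "
                "the designed homology length)"
            )

    h1 = element.sequence
    h2_edits = []
    truth_events = []
    # plant homologies left to right on h1; apply sequence edits right to left
    for (start, end), ev in spans:
        if ev.kind == "deletion":
            h1, _, (ns, ne) = plant_deletion(
                h1, start, end, ev.designed_mh, rng, ev.mismatch_positions
            )
            h2_edits.append(("del", ns, ne))
            truth_events.append(
                {"segment": [ns, ne], "designed_mh": ev.designed_mh,
                 "kind": "deletion", "inserted_bases": ""}
            )
        elif ev.kind == "duplication":
            h2_edits.append(("dup", start, end))
            truth_events.append(
                {"segment": [start, end], "designed_mh": end - start,
                 "kind": "duplication", "inserted_bases": ""}
            )
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    h2 = h1
    for op, start, end in sorted(h2_edits, reverse=True, key=lambda x: x[1]):
        if op == "del":
            h2 = h2[:start] + h2[end:]
        else:
            h2 = h2[:start] + h2[start:end] + h2[start:]
    e1 = VNTRElement(id=element.id + "_h1", subfamily=element.subfamily, sequence=h1)
    e2 = VNTRElement(id=element.id + "_h2", subfamily=element.subfamily, sequence=h2)
    return e1, e2, truth_events


def random_element(seed: int, length: int = 500, element_id: str = "rand") -> VNTRElement:
    """A GC-rich random sequence with no repeat structure (null element)."""
    rng = np.random.default_rng(seed)
    return VNTRElement(id=element_id, subfamily="random", sequence=_rand_seq(rng, length))


def make_random_planted_pair(
    seed: int,
    seq_len: int = 500,
    indel_len_range: tuple[int, int] = (37, 150),
    mh_max: int = 42,
    designed_mh: int | None = None,
):
    """One ortholog pair on a structureless background with one planted event.

    The background is random GC-rich sequence, so the planted homology is the
    *only* homology at the breakpoints; the pair is rejection-sampled until
    the exact right-side homology of the planted representation equals the
    designed value and the representation is left-normalized.  Returns
    (hap_long, hap_short, truth dict).
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = _rand_seq(rng, seq_len)
        lo, hi = indel_len_range
        length = int(rng.integers(lo, hi + 1))
        mh = int(rng.integers(0, min(mh_max, length) + 1)) if designed_mh is None else designed_mh
        start = int(rng.integers(1, seq_len - length - mh - 1))
        end = start + length
        h1, h2, (ns, ne) = plant_deletion(seq, start, end, mh, rng)
        # verify: the designed homology is exact and maximal, the
        # representation stable under left-normalization
        S, Rf = h1[ns:ne], h1[ne:]
        got = 0
        for x, y in zip(S, Rf):
            if x != y:
                break
            got += 1
        if got != mh:
            continue
        if ns > 0 and h1[ns - 1] == h1[ne - 1]:
            continue
        truth = {"segment": [ns, ne], "designed_mh": mh, "kind": "deletion"}
        e1 = VNTRElement(id=f"rp{seed}_h1", subfamily="random", sequence=h1)
        e2 = VNTRElement(id=f"rp{seed}_h2", subfamily="random", sequence=h2)
        return e1, e2, truth
    raise RuntimeError("could not plant a clean event (rejection limit reached)")


# ----------------------------------------------------------------------
# FASTA I/O for element sets
# ----------------------------------------------------------------------

def write_elements_fasta(elements: list[VNTRElement], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for el in elements:
            header = f">{el.id}|{el.subfamily}"
            if el.source:
                header += f"|{el.source}"
            fh.write(header + "\n")
            for i in range(0, len(el.sequence), width):
                fh.write(el.sequence[i : i + width] + "\n")


def read_elements_fasta(path) -> list[VNTRElement]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) < 2:
            raise ValueError(
                f"element header {rec.description!r}: expected 'id|subfamily[|locus]'"
            )
        out.append(
            VNTRElement(
                id=parts[0],
                subfamily=parts[1],
                sequence=str(rec.seq).upper(),
                source=parts[2] if len(parts) > 2 else None,
            )
        )
    return out


def write_truth_jsonl(truths: list[SimTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(json.dumps({
                "element_id": t.element_id,
                "generating_tokens": [list(x) for x in t.generating_tokens],
                "mutations": [list(m) for m in t.mutations],
                "token_indels": [list(x) for x in t.token_indels],
                "planted_events": t.planted_events,
            }) + "\n")
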