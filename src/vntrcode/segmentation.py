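"""Decomposition of VNTR sequences into repeat-unit token strings.

The central step of the analysis: given a nucleotide VNTR sequence and a
repeat-unit library, produce the element's *repeat schema* — an ordered,
gap-free tiling of the sequence by RU tokens, each labelled with the best
matching type/variant.  The paper's manual unit-splitting procedure is
formalized here as a minimum-cost segmentation:

    D(0) = 0
    D(j) = min over i < j, (j - i) in [W_min, W_max] of
               D(i) + unitcost(i, j) + tau

where ``unitcost`` is the minimum Levenshtein distance of ``seq[i:j]`` to any
library consensus, an unclassified token ('X') is available at cost
``ceil(0.5 * (j - i))``, and ``tau`` is a per-token startup penalty that
discourages over-segmentation.  Ties are broken deterministically: fewer
tokens, then lexicographically smallest code string, then leftmost-longest
first token.  The final token may be shorter than ``W_min``; it is matched
against equal-length prefixes of the consensi and flagged truncated.

De-novo unit discovery (:func:`discover_units`) follows the sort-by-length /
sort-by-sequence / majority-rule procedure used to derive the RU consensus
sequences in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._align import encode, unit_cost_table
from .ru_library import RULibrary

__all__ = [
    "VNTRElement",
    "Token",
    "RepeatSchema",
    "SegmentationParams",
    "SegmentationError",
    "AssemblyGapError",
    "segment_vntr",
    "classify_token",
    "discover_units",
    "UnitCluster",
    "decode_code_string",
    "schemata_to_frame",
]


class SegmentationError(ValueError):
    pass


class AssemblyGapError(SegmentationError):
    """Too large a fraction of the sequence is N (assembly gap)."""


def render_label(code: str, tag: str) -> str:
    """Token label: primes attach directly (B'), other tags via a dot (C.T)."""
    if not tag:
        return code
    if set(tag) == {"'"}:
        return code + tag
    return code + "." + tag


@dataclass(frozen=True)
class VNTRElement:
    """A pre-extracted VNTR nucleotide sequence with its element labels."""

    id: str
    subfamily: str
    sequence: str
    source: str | None = None  # "assembly:chr:start-end:strand", informational


@dataclass(frozen=True)
class Token:
    type_code: str
    variant_tag: str
    start: int
    end: int
    edit_distance: int
    identity: float
    truncated: bool = False

    @property
    def label(self) -> str:
        return render_label(self.type_code, self.variant_tag)

    @property
    def key(self) -> tuple[str, str]:
        return (self.type_code, self.variant_tag)


@dataclass
class RepeatSchema:
    element_id: str
    tokens: list[Token]
    subfamily: str = ""

    @property
    def code_string(self) -> str:
        return "-".join(t.label for t in self.tokens)

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [t.key for t in self.tokens]


def decode_code_string(code_string: str) -> list[tuple[str, str]]:
    """Parse "A-B'-C.T-X" into (type_code, variant_tag) pairs.

    The first character of each dash-separated field is the type code; a
    remainder made of primes attaches directly (B', C''), any other tag is
    introduced by a dot (C.T for the superscript-T variant).
    """
    if not code_string:
        return []
    out = []
    for tok in code_string.split("-"):
        if not tok:
            raise ValueError(f"empty token in code string {code_string!r}")
        code, rest = tok[0], tok[1:]
        if rest.startswith("."):
            rest = rest[1:]
        elif rest and set(rest) != {"'"}:
            raise ValueError(f"cannot parse token {tok!r}")
        out.append((code, rest))
    return out


@dataclass(frozen=True)
class SegmentationParams:
    w_min: int = 25
    w_max: int = 60
    tau: int = 2
    identity_threshold: float = 0.75
    max_n_fraction: float = 0.10
    cluster_identity: float = 0.90


def _sorted_entries(lib: RULibrary) -> list[tuple[str, str, str]]:
    # lexicographic entry order makes "first minimum wins" deterministic
    return sorted(lib.entries(), key=lambda e: (e[0], e[1]))


def _identity(distance: int, unit_len: int, cons_len: int) -> float:
    return 1.0 - distance / max(unit_len, cons_len)


# ----------------------------------------------------------------------
# Tokenizer
# ----------------------------------------------------------------------

def segment_vntr(
    element: VNTRElement,
    lib: RULibrary,
    params: SegmentationParams | None = None,
) -> RepeatSchema:
    """Optimal repeat-unit tiling of one element's VNTR sequence."""
    params = params or SegmentationParams()
    if not lib.units:
        raise SegmentationError("empty repeat-unit library")
    seq = element.sequence.upper()
    n = len(seq)
    schema = RepeatSchema(element_id=element.id, tokens=[], subfamily=element.subfamily)
    if n == 0:
        return schema
    if seq.count("N") > params.max_n_fraction * n:
        raise AssemblyGapError(
            f"element {element.id}: more than "
            f"{params.max_n_fraction:.0%} of the sequence is N (assembly gap)"
        )
    entries = _sorted_entries(lib)
    enc = encode(seq)
    ents = np.concatenate([encode(c) for _, _, c in entries])
    lens = np.array([len(c) for _, _, c in entries], dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)
    cost_tbl, idx_tbl = unit_cost_table(enc, ents, offs, lens, params.w_max)

    # pass 1: plain integer min-cost DP
    INF = math.inf
    cost = [INF] * (n + 1)
    cost[0] = 0
    wmin, wmax, tau = params.w_min, params.w_max, params.tau

    def _options(i: int, j: int):
        """Candidate (unitcost, label, entry_index, truncated) for seq[i:j]."""
        w = j - i
        out = []
        if wmin <= w <= wmax:
            e = idx_tbl[i, w]
            if e >= 0:
                out.append((int(cost_tbl[i, w]), render_label(entries[e][0], entries[e][1]), int(e), False))
            out.append(((w + 1) // 2, "X", -1, False))
        elif j == n and 0 < w < wmin:
            # terminal truncation: equal-length consensus prefixes
            bestd, beste = (w + 1) // 2, -1
            sub = seq[i:j]
            for e, (_c, _t, cons) in enumerate(entries):
                if len(cons) < w:
                    continue
                d = sum(1 for x, y in zip(sub, cons[:w]) if x != y or x == "N")
                if d < bestd:
                    bestd, beste = d, e
            label = "X" if beste < 0 else render_label(*entries[beste][:2])
            out.append((bestd, label, beste, True))
        return out

    for j in range(1, n + 1):
        lo = max(0, j - wmax)
        for i in range(lo, j):
            if cost[i] is INF:
                continue
            for c, _label, _e, _tr in _options(i, j):
                if cost[i] + c + tau < cost[j]:
                    cost[j] = cost[i] + c + tau

    if cost[n] is INF:
        raise SegmentationError(
            f"element {element.id}: no tiling with unit lengths in "
            f"[{wmin}, {wmax}] covers the sequence"
        )

    # pass 2: tie-broken reconstruction among minimum-cost tilings.
    # State per position: (n_tokens, labels, neg_ends, backpointer).
    state: list[tuple | None] = [None] * (n + 1)
    state[0] = (0, (), (), None)
    for j in range(1, n + 1):
        best = None
        lo = max(0, j - wmax)
        for i in range(lo, j):
            if state[i] is None:
                continue
            for c, label, e, trunc in _options(i, j):
                if cost[i] + c + tau != cost[j]:
                    continue
                ntok, labels, negends, _ = state[i]
                cand = (
                    ntok + 1,
                    labels + (label,),
                    negends + (-j,),
                    (i, c, label, e, trunc),
                )
                if best is None or cand[:3] < best[:3]:
                    best = cand
        state[j] = best

    tokens: list[Token] = []
    j = n
    while j > 0:
        i, c, label, e, trunc = state[j][3]
        w = j - i
        if e >= 0:
            code, tag, cons = entries[e]
            cons_len = w if trunc else len(cons)
            ident = _identity(c, w, cons_len)
            if ident < params.identity_threshold:
                code, tag = "X", ""
        else:
            code, tag, ident = "X", "", 0.0
        tokens.append(
            Token(
                type_code=code,
                variant_tag=tag,
                start=i,
                end=j,
                edit_distance=c,
                identity=round(ident, 4),
                truncated=trunc,
            )
        )
        j = i
    schema.tokens = tokens[::-1]
    return schema


# ----------------------------------------------------------------------
# Classification of a single pre-split unit
# ----------------------------------------------------------------------

def classify_token(
    unit: str,
    lib: RULibrary,
    identity_threshold: float = 0.75,
) -> tuple[str, str, int]:
    """Assign one unit to (type_code, variant_tag) by minimum edit distance.

    The best base type is chosen first (a type's score is the minimum
    distance over its base consensus and all of its variants), then the best
    variant within that type.  Units below the identity threshold go to the
    sink class 'X'.
    """
    if not unit:
        raise SegmentationError("cannot classify an empty unit")
    unit = unit.upper()
    by_type: dict[str, list[tuple[int, str, int]]] = {}
    for code, tag, cons in _sorted_entries(lib):
        d = edlib.align(unit, cons, task="distance")["editDistance"]
        by_type.setdefault(code, []).append((d, tag, len(cons)))
    best_code = min(by_type, key=lambda c: (min(x[0] for x in by_type[c]), c))
    d, tag, cons_len = min(by_type[best_code], key=lambda x: (x[0], x[1]))
    if _identity(d, len(unit), cons_len) < identity_threshold:
        return ("X", "", d)
    return (best_code, tag, d)


# ----------------------------------------------------------------------
# De-novo unit discovery
# ----------------------------------------------------------------------

@dataclass
class UnitCluster:
    consensus: str
    support: int
    members: list[int]  # indices into the input unit list
    tie_columns: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.consensus)


def _majority_consensus(seqs: list[str]) -> tuple[str, list[int]]:
    """Per-column majority over equal-length strings; alphabetical tie-break."""
    arr = np.array([list(s) for s in seqs])
    cols, ties = [], []
    for j in range(arr.shape[1]):
        vals, counts = np.unique(arr[:, j], return_counts=True)
        top = counts.max()
        winners = sorted(vals[counts == top])
        if len(winners) > 1:
            ties.append(j)
        cols.append(winners[0])
    return "".join(cols), ties


def discover_units(
    units: list[str],
    cluster_identity: float = 0.90,
) -> list[UnitCluster]:
    """Cluster pre-split units and derive one majority consensus per cluster.

    Units are grouped by exact length first, then single-linkage clustered
    within each length class at the given identity; clusters are returned
    ordered by support (descending).
    """
    if not units:
        raise SegmentationError("discover_units: empty input")
    units = [u.upper() for u in units]
    by_len: dict[int, list[int]] = {}
    for i, u in enumerate(units):
        if not u:
            raise SegmentationError("discover_units: empty unit string")
        by_len.setdefault(len(u), []).append(i)

    clusters: list[UnitCluster] = []
    for L, idxs in sorted(by_len.items()):
        parent = {i: i for i in idxs}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a_pos, a in enumerate(idxs):
            for b in idxs[a_pos + 1 :]:
                d = edlib.align(units[a], units[b], task="distance")["editDistance"]
                if 1.0 - d / L >= cluster_identity:
                    parent[find(a)] = find(b)
        groups: dict[int, list[int]] = {}
        for i in idxs:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            cons, ties = _majority_consensus([units[i] for i in members])
            clusters.append(
                UnitCluster(
                    consensus=cons,
                    support=len(members),
                    members=sorted(members),
                    tie_columns=ties,
                )
            )
    clusters.sort(key=lambda c: (-c.support, c.consensus))
    return clusters


# ----------------------------------------------------------------------
# Tabular output
# ----------------------------------------------------------------------

def schemata_to_frame(schemata: list[RepeatSchema]) -> pd.DataFrame:
    rows = []
    for s in schemata:
        for k, t in enumerate(s.tokens):
            rows.append(
                {
                    "element_id": s.element_id,
                    "token_index": k,
                    "type_code": t.type_code,
                    "variant_tag": t.variant_tag,
                    "start": t.start,
                    "end": t.end,
                    "edit_distance": t.edit_distance,
                    "identity": t.identity,
                    "truncated": t.truncated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "element_id",
            "token_index",
            "type_code",
            "variant_tag",
            "start",
            "end",
            "edit_distance",
            "identity",
            "truncated",
        ],
    )
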