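"""Copy-number remodelling between orthologous VNTRs.

Orthologous elements in two species descend from one ancestral insertion
without an RNA intermediate, so every difference between their VNTRs arose
at the DNA level.  This module calls repeat-unit copy-number indels between
such a pair, measures the breakpoint microhomology that is the signature of
slippage/MMEJ/MMBIR-type mechanisms, and attaches mechanism *compatibility*
labels:

* ``precise_ru_indel`` — the indel is a whole number of repeat units with
  both breakpoints on token boundaries;
* ``ru_conversion_microindel`` — a micro-indel (<= 5 bp) that converts the
  containing repeat unit into a different type (e.g. A -> C by a 3 bp
  deletion);
* ``mh_mediated`` — breakpoint microhomology of at least ``mh_min`` bp;
* ``slippage_compatible`` — indel length plus microhomology within one
  Okazaki-fragment span (~200 bp), the reach of replication slippage;
* ``nahr_compatible`` — microhomology at least the ~34 bp minimal efficient
  processing segment of non-allelic homologous recombination;
* ``mmej_signature`` — microhomology plus inserted junction bases.

Labels are compatibilities, not exclusive mechanism calls, and indel
polarity is left unresolved: without an outgroup it cannot be decided
whether the long or the short allele is ancestral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from difflib import SequenceMatcher

import pandas as pd

from ._align import encode, gotoh
from .ru_library import RULibrary
from .segmentation import (
    RepeatSchema,
    SegmentationParams,
    VNTRElement,
    classify_token,
    segment_vntr,
)

__all__ = [
    "MechanismConfig",
    "IndelEvent",
    "OrthologPair",
    "make_pair",
    "align_pair",
    "measure_microhomology",
    "classify_mechanism",
    "compare_pair",
    "left_normalize",
    "events_to_frame",
    "events_to_jsonl",
]


@dataclass(frozen=True)
class MechanismConfig:
    mh_min: int = 5
    nahr_min: int = 34
    slippage_window: int = 200
    relaxed_identity: float = 0.9
    merge_distance: int = 10
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1

    def __post_init__(self):
        if not (0 < self.mh_min <= self.nahr_min):
            raise ValueError("require 0 < mh_min <= nahr_min")
        if self.slippage_window <= 0:
            raise ValueError("slippage_window must be positive")


@dataclass
class IndelEvent:
    """One copy-number difference, reported on the longer sequence."""

    pair_id: str
    start: int  # segment on seq_long, 0-based half-open, left-normalized
    end: int
    inserted_bases: str = ""  # sequence carried by seq_short in place of segment
    merged: bool = False
    mh_exact_left: int = 0
    mh_exact_right: int = 0
    mh_relaxed: int = 0
    token_boundary_aligned: bool = False
    converted_tokens: list[tuple[str, str]] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        seg = self.end - self.start
        return seg if seg > 0 else len(self.inserted_bases)

    @property
    def tract_distance(self) -> int:
        return self.length


@dataclass
class OrthologPair:
    id: str
    seq_long: VNTRElement
    seq_short: VNTRElement
    schema_long: RepeatSchema
    schema_short: RepeatSchema


def make_pair(
    pair_id: str,
    a: VNTRElement,
    b: VNTRElement,
    lib: RULibrary,
    params: SegmentationParams | None = None,
) -> OrthologPair:
    """Order two orthologs by length (ties by sequence) and tokenize both."""
    if len(b.sequence) > len(a.sequence) or (
        len(b.sequence) == len(a.sequence) and b.sequence < a.sequence
    ):
        a, b = b, a
    return OrthologPair(
        id=pair_id,
        seq_long=a,
        seq_short=b,
        schema_long=segment_vntr(a, lib, params),
        schema_short=segment_vntr(b, lib, params),
    )


# ----------------------------------------------------------------------
# Indel calling
# ----------------------------------------------------------------------

def left_normalize(long_seq: str, start: int, end: int, inserted: str):
    """Canonical (maximally 5'-shifted) representation of an indel.

    Pure deletions shift left while the flank base equals the last segment
    base; pure insertions rotate the inserted string leftwards likewise.
    Complex replacement events (segment and inserted bases both non-empty)
    are left where the alignment put them.
    """
    if end > start and not inserted:
        while start > 0 and long_seq[start - 1] == long_seq[end - 1]:
            start -= 1
            end -= 1
    elif end == start and inserted:
        while start > 0 and long_seq[start - 1] == inserted[-1]:
            inserted = long_seq[start - 1] + inserted[:-1]
            start -= 1
            end -= 1
    return start, end, inserted


def _window_events(long_seq, short_seq, wls, wle, wss, wse, cfg):
    """Affine-gap alignment of one candidate window; raw indels in long coords."""
    a = long_seq[wls:wle]
    b = short_seq[wss:wse]
    if not a and not b:
        return []
    if not a:
        return [(wls, wls, b)]
    if not b:
        return [(wls, wle, "")]
    ops, _score = gotoh(
        encode(a), encode(b), cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend
    )
    events = []
    ia, ib = 0, 0
    for op in ops:
        if op == 0:
            ia += 1
            ib += 1
        elif op == 1:  # gap in short: segment present only in long
            if events and events[-1][1] == wls + ia and not events[-1][2]:
                s, _e, ins = events.pop()
                events.append((s, wls + ia + 1, ins))
            else:
                events.append((wls + ia, wls + ia + 1, ""))
            ia += 1
        else:  # gap in long: bases present only in short
            if events and events[-1][1] == wls + ia and events[-1][0] == events[-1][1]:
                s, e, ins = events.pop()
                events.append((s, e, ins + b[ib]))
            else:
                events.append((wls + ia, wls + ia, b[ib]))
            ib += 1
    return events


def align_pair(pair: OrthologPair, cfg: MechanismConfig | None = None) -> list[IndelEvent]:
    """Two-stage indel calling between the orthologs of a pair.

    A token-level edit script over the two code strings localizes candidate
    copy-number differences; a nucleotide-level affine-gap alignment within
    each flanked window fixes the breakpoints.  Events are left-normalized
    and events closer than ``merge_distance`` are merged (flagged).
    Identical sequences yield an empty list.
    """
    cfg = cfg or MechanismConfig()
    L = pair.seq_long.sequence
    S = pair.seq_short.sequence
    if L == S:
        return []
    kl = pair.schema_long.keys
    ks = pair.schema_short.keys
    sm = SequenceMatcher(None, kl, ks, autojunk=False)
    raw: list[tuple[int, int, str]] = []
    windows: list[list[int]] = []
    tl0 = pair.schema_long.tokens
    ts0 = pair.schema_short.tokens
    regions = []
    for op in sm.get_opcodes():
        if op[0] != "equal":
            regions.append(op)
            continue
        # token keys match, but the underlying bases may still differ in
        # length (e.g. runs of unclassified tokens): verify the content
        _tag, i1, i2, j1, j2 = op
        sub_l = L[tl0[i1].start : tl0[i2 - 1].end] if i2 > i1 else ""
        sub_s = S[ts0[j1].start : ts0[j2 - 1].end] if j2 > j1 else ""
        if len(sub_l) != len(sub_s):
            regions.append(("replace", i1, i2, j1, j2))
    # merge adjacent non-equal opcode regions separated by < 2 matched tokens
    grouped: list[list] = []
    for op in regions:
        if grouped and op[1] - grouped[-1][-1][2] < 2:
            grouped[-1].append(op)
        else:
            grouped.append([op])
    tl = pair.schema_long.tokens
    ts = pair.schema_short.tokens
    for group in grouped:
        i1, i2 = group[0][1], group[-1][2]
        j1, j2 = group[0][3], group[-1][4]
        # Inside a run of identical units the token edit script may point at
        # the wrong copy: widen the window across whole runs of any unit
        # type seen in the edited region, then add one anchor token.
        edge = set(kl[i1:i2]) | set(ks[j1:j2])
        i1a, i2a, j1a, j2a = i1, i2, j1, j2
        while i1a > 0 and kl[i1a - 1] in edge:
            i1a -= 1
        while i2a < len(kl) and kl[i2a] in edge:
            i2a += 1
        while j1a > 0 and ks[j1a - 1] in edge:
            j1a -= 1
        while j2a < len(ks) and ks[j2a] in edge:
            j2a += 1
        i1a, i2a = max(0, i1a - 1), min(len(tl), i2a + 1)
        j1a, j2a = max(0, j1a - 1), min(len(ts), j2a + 1)
        windows.append([i1a, i2a, j1a, j2a])
    # widened windows may overlap; merge them before aligning
    merged_windows: list[list[int]] = []
    for w in windows:
        if merged_windows and w[0] <= merged_windows[-1][1]:
            prev = merged_windows[-1]
            prev[1] = max(prev[1], w[1])
            prev[2] = min(prev[2], w[2])
            prev[3] = max(prev[3], w[3])
        else:
            merged_windows.append(w)
    for i1a, i2a, j1a, j2a in merged_windows:
        wls = tl[i1a].start if tl else 0
        wle = tl[i2a - 1].end if i2a > i1a else wls
        wss = ts[j1a].start if ts else 0
        wse = ts[j2a - 1].end if j2a > j1a else wss
        raw.extend(_window_events(L, S, wls, wle, wss, wse, cfg))

    # normalize, sort, merge
    norm = [left_normalize(L, s, e, ins) for s, e, ins in raw]
    norm.sort()
    merged: list[tuple[int, int, str, bool]] = []
    for s, e, ins in norm:
        if merged and s - merged[-1][1] < cfg.merge_distance:
            ps, pe, pins, _ = merged.pop()
            # short-side bases between the two events are the matched run
            mid = L[pe:s]
            merged.append((ps, e, pins + mid + ins, True))
        else:
            merged.append((s, e, ins, False))
    events = [
        IndelEvent(pair_id=pair.id, start=s, end=e, inserted_bases=ins, merged=m)
        for s, e, ins, m in merged
        if e > s or ins
    ]
    return events


# ----------------------------------------------------------------------
# Microhomology
# ----------------------------------------------------------------------

def _exact_prefix(a: str, b: str) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            break
        m += 1
    return m


def _relaxed_extent(a: str, b: str, identity: float) -> int:
    """Longest m with running identity of a[:m] vs b[:m] >= threshold,
    ending on a matching base."""
    best = 0
    matches = 0
    for m, (x, y) in enumerate(zip(a, b), start=1):
        if x == y:
            matches += 1
            if matches / m >= identity:
                best = m
    return best


def measure_microhomology(
    pair: OrthologPair,
    event: IndelEvent,
    cfg: MechanismConfig | None = None,
) -> IndelEvent:
    """Populate the microhomology fields of one event.

    With segment S, left flank Lf and right flank Rf on the sequence that
    carries the extra bases: ``mh_exact_right`` is the longest exact match
    of S's prefix with Rf, ``mh_exact_left`` the longest exact match of S's
    suffix with Lf, and ``mh_relaxed`` extends greedily tolerating
    mismatches while the running identity stays at or above
    ``relaxed_identity`` (the two species have diverged since the event, so
    identity inside a microhomology need not be 100%).
    """
    cfg = cfg or MechanismConfig()
    L = pair.seq_long.sequence
    if event.end > event.start:
        S = L[event.start : event.end]
        Lf = L[: event.start]
        Rf = L[event.end :]
    elif event.inserted_bases:
        S = event.inserted_bases
        Lf = L[: event.start]
        Rf = L[event.start :]
    else:
        raise ValueError("window does not contain an indel")
    mh_right = _exact_prefix(S, Rf)
    mh_left = _exact_prefix(S[::-1], Lf[::-1])
    relaxed = max(
        _relaxed_extent(S, Rf, cfg.relaxed_identity),
        _relaxed_extent(S[::-1], Lf[::-1], cfg.relaxed_identity),
        mh_right,
        mh_left,
    )
    event.mh_exact_right = mh_right
    event.mh_exact_left = mh_left
    event.mh_relaxed = relaxed
    return event


# ----------------------------------------------------------------------
# Mechanism labels
# ----------------------------------------------------------------------

def classify_mechanism(
    event: IndelEvent,
    pair: OrthologPair,
    lib: RULibrary,
    cfg: MechanismConfig | None = None,
) -> IndelEvent:
    """Attach mechanism-compatibility labels (labels may co-occur)."""
    cfg = cfg or MechanismConfig()
    labels: set[str] = set()
    tokens = pair.schema_long.tokens
    L = pair.seq_long.sequence
    boundaries = {t.start for t in tokens} | {len(L)}
    # a left-normalized indel is one representative of an ambiguity range:
    # enumerate the equivalent right-shifted representations as well
    reps = [(event.start, event.end)]
    s, e = event.start, event.end
    while e < len(L) and e > s and L[s] == L[e] and len(reps) < 200:
        s += 1
        e += 1
        reps.append((s, e))
    seg = event.end - event.start
    event.token_boundary_aligned = seg > 0 and any(
        rs in boundaries and re in boundaries for rs, re in reps
    )
    if event.token_boundary_aligned and not event.inserted_bases:
        rs, re = next(
            (r for r in reps if r[0] in boundaries and r[1] in boundaries)
        )
        covered = [t for t in tokens if rs <= t.start and t.end <= re]
        if covered and all(t.type_code != "X" for t in covered):
            labels.add("precise_ru_indel")
    if 0 < event.length <= 5:
        hosted = next(
            (
                (t, rs, re)
                for t in tokens
                for rs, re in reps
                if t.start <= rs and re <= t.end
            ),
            None,
        )
        if hosted is not None and hosted[0].type_code != "X":
            host, rs, re = hosted
            short_version = (
                L[host.start : rs] + event.inserted_bases + L[re : host.end]
            )
            if short_version:
                to_code, _tag, _d = classify_token(short_version, lib)
                if to_code not in ("X", host.type_code):
                    labels.add("ru_conversion_microindel")
                    event.converted_tokens = [(host.type_code, to_code)]
    if event.mh_relaxed >= cfg.mh_min:
        labels.add("mh_mediated")
    if event.length + event.mh_relaxed <= cfg.slippage_window:
        labels.add("slippage_compatible")
    if event.mh_relaxed >= cfg.nahr_min:
        labels.add("nahr_compatible")
    if event.mh_relaxed >= cfg.mh_min and event.inserted_bases and event.end > event.start:
        labels.add("mmej_signature")
    if not labels:
        labels.add("unclassified")
    event.labels = labels
    return event


def compare_pair(
    pair: OrthologPair,
    lib: RULibrary,
    cfg: MechanismConfig | None = None,
) -> list[IndelEvent]:
    """Full comparison: call, measure and classify all events of a pair."""
    cfg = cfg or MechanismConfig()
    events = align_pair(pair, cfg)
    for ev in events:
        measure_microhomology(pair, ev, cfg)
        classify_mechanism(ev, pair, lib, cfg)
    return events


# ----------------------------------------------------------------------
# Output
# ----------------------------------------------------------------------

def events_to_frame(events: list[IndelEvent]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": ev.pair_id,
            "segment_start": ev.start,
            "segment_end": ev.end,
            "length": ev.length,
            "mh_exact_left": ev.mh_exact_left,
            "mh_exact_right": ev.mh_exact_right,
            "mh_relaxed": ev.mh_relaxed,
            "inserted_bases": ev.inserted_bases,
            "merged": ev.merged,
            "labels": ",".join(sorted(ev.labels)),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "segment_start",
            "segment_end",
            "length",
            "mh_exact_left",
            "mh_exact_right",
            "mh_relaxed",
            "inserted_bases",
            "merged",
            "labels",
        ],
    )


def events_to_jsonl(events: list[IndelEvent]) -> str:
    lines = []
    for ev in events:
        lines.append(
            json.dumps(
                {
                    "pair_id": ev.pair_id,
                    "segment": [ev.start, ev.end],
                    "length": ev.length,
                    "inserted_bases": ev.inserted_bases,
                    "merged": ev.merged,
                    "mh_exact_left": ev.mh_exact_left,
                    "mh_exact_right": ev.mh_exact_right,
                    "mh_relaxed": ev.mh_relaxed,
                    "token_boundary_aligned": ev.token_boundary_aligned,
                    "converted_tokens": ev.converted_tokens,
                    "labels": sorted(ev.labels),
                }
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
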