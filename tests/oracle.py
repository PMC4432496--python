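"""Independent oracles used by the test suite.

These deliberately avoid the package's own numba kernels: distances come
from edlib, segmentation costs from exhaustive enumeration of all tilings,
microhomology from a naive character scan.
"""

import math
from functools import lru_cache

import edlib


def bruteforce_segmentation_cost(seq, lib, params):
    """Minimum tiling cost by exhaustive enumeration of all segmentations.

    A token of width w in [w_min, w_max] costs min(library Levenshtein,
    ceil(w/2)) + tau; the final token may be shorter than w_min, matched
    against equal-length consensus prefixes at Hamming cost.
    """
    n = len(seq)
    entries = [cons for _code, _tag, cons in lib.entries()]

    @lru_cache(maxsize=None)
    def unit_cost(i, j):
        sub = seq[i:j]
        best = math.ceil(0.5 * (j - i))
        for cons in entries:
            d = edlib.align(sub, cons, task="distance")["editDistance"]
            best = min(best, d)
        return best

    @lru_cache(maxsize=None)
    def trunc_cost(i):
        sub = seq[i:]
        best = math.ceil(0.5 * (n - i))
        for cons in entries:
            if len(cons) >= len(sub):
                best = min(best, sum(1 for x, y in zip(sub, cons) if x != y))
        return best

    best = [math.inf] * (n + 1)

    def rec(i, acc):
        if acc >= best[i]:
            return
        best[i] = acc
        if i == n:
            return
        for w in range(params.w_min, params.w_max + 1):
            if i + w > n:
                break
            rec(i + w, acc + unit_cost(i, i + w) + params.tau)
        if n - i < params.w_min:
            rec(n, acc + trunc_cost(i) + params.tau)

    rec(0, 0)
    return best[n]


def scan_mh_right(segment, right_flank):
    m = 0
    for x, y in zip(segment, right_flank):
        if x != y:
            break
        m += 1
    return m


def scan_mh_left(segment, left_flank):
    m = 0
    for x, y in zip(reversed(segment), reversed(left_flank)):
        if x != y:
            break
        m += 1
    return m


def schema_cost(schema, tau):
    """Total DP cost of a produced schema (token costs plus startup penalty)."""
    return sum(t.edit_distance for t in schema.tokens) + tau * len(schema.tokens)
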