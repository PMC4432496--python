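"""Low-level alignment kernels (numba-compiled).

Two primitives used throughout the package:

* :func:`unit_cost_table` — for every start position ``i`` and window width
  ``w`` of a nucleotide sequence, the minimum Levenshtein distance between
  ``seq[i:i+w]`` and any repeat-unit consensus in a library.  One row of the
  classic edit-distance matrix is swept per library entry, so the distances
  for *all* window widths at a given start come out of a single DP pass.
* :func:`gotoh` — global affine-gap alignment (Gotoh's three-state DP) of two
  short windows, used to fix indel breakpoints at nucleotide resolution.

Bases are encoded A=0, C=1, G=2, T=3, N=4; N mismatches everything,
including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in BASE_CODES.items():
    _LUT[ord(_b)] = _c

BIG = 1 << 30


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes; reject other characters."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted(set(seq) - set(BASE_CODES))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return arr


@njit(cache=True)
def unit_cost_table(seq, ents, offs, lens, wmax):  # pragma: no cover - numba
    n = seq.shape[0]
    ne = lens.shape[0]
    best = np.full((n, wmax + 1), BIG, dtype=np.int32)
    bestidx = np.full((n, wmax + 1), -1, dtype=np.int32)
    row = np.empty(wmax + 1, dtype=np.int32)
    prev = np.empty(wmax + 1, dtype=np.int32)
    for i in range(n):
        wlim = min(wmax, n - i)
        for e in range(ne):
            Le = lens[e]
            o = offs[e]
            for j in range(wlim + 1):
                prev[j] = j
            for k in range(1, Le + 1):
                row[0] = k
                ck = ents[o + k - 1]
                for j in range(1, wlim + 1):
                    sj = seq[i + j - 1]
                    if sj == ck and sj < 4:
                        m = prev[j - 1]
                    else:
                        m = prev[j - 1] + 1
                    if prev[j] + 1 < m:
                        m = prev[j] + 1
                    if row[j - 1] + 1 < m:
                        m = row[j - 1] + 1
                    row[j] = m
                for j in range(wlim + 1):
                    prev[j] = row[j]
            for w in range(1, wlim + 1):
                if prev[w] < best[i, w]:
                    best[i, w] = prev[w]
                    bestidx[i, w] = e
    return best, bestidx


@njit(cache=True)
def levenshtein(a, b):  # pragma: no cover - numba
    la, lb = a.shape[0], b.shape[0]
    prev = np.arange(lb + 1).astype(np.int32)
    row = np.empty(lb + 1, dtype=np.int32)
    for k in range(1, la + 1):
        row[0] = k
        ck = a[k - 1]
        for j in range(1, lb + 1):
            sj = b[j - 1]
            if sj == ck and sj < 4:
                m = prev[j - 1]
            else:
                m = prev[j - 1] + 1
            if prev[j] + 1 < m:
                m = prev[j] + 1
            if row[j - 1] + 1 < m:
                m = row[j - 1] + 1
            row[j] = m
        for j in range(lb + 1):
            prev[j] = row[j]
    return prev[lb]


# Gotoh three-state global alignment.  A gap of length L costs
# gap_open + L * gap_ext.  Returned ops: 0 = aligned column (match or
# mismatch), 1 = gap in b (consumes a), 2 = gap in a (consumes b).
@njit(cache=True)
def gotoh(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    NEG = -(1 << 30)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_ext * i
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_ext * j
        pY[0, j] = 1
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            bm = M[i - 1, j - 1]
            pm = 0
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                pm = 1
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                pm = 2
            M[i, j] = bm + s
            pM[i, j] = pm
            # X: gap in b, consumes a[i-1]
            bx = M[i - 1, j] + gap_open + gap_ext
            px = 0
            if X[i - 1, j] + gap_ext > bx:
                bx = X[i - 1, j] + gap_ext
                px = 1
            if Y[i - 1, j] + gap_open + gap_ext > bx:
                bx = Y[i - 1, j] + gap_open + gap_ext
                px = 2
            X[i, j] = bx
            pX[i, j] = px
            # Y: gap in a, consumes b[j-1]
            by = M[i, j - 1] + gap_open + gap_ext
            py = 0
            if Y[i, j - 1] + gap_ext > by:
                by = Y[i, j - 1] + gap_ext
                py = 1
            if X[i, j - 1] + gap_open + gap_ext > by:
                by = X[i, j - 1] + gap_open + gap_ext
                py = 2
            Y[i, j] = by
            pY[i, j] = py
    # traceback
    state = 0
    bestv = M[n, m]
    if X[n, m] > bestv:
        bestv = X[n, m]
        state = 1
    if Y[n, m] > bestv:
        bestv = Y[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            k += 1
            nxt = pM[i, j]
            i -= 1
            j -= 1
            state = nxt
        elif state == 1:
            ops[k] = 1
            k += 1
            nxt = pX[i, j]
            i -= 1
            if nxt == 0:
                state = 0
            elif nxt == 2:
                state = 2
        else:
            ops[k] = 2
            k += 1
            nxt = pY[i, j]
            j -= 1
            if nxt == 0:
                state = 0
            elif nxt == 2:
                state = 1
    return ops[:k][::-1].copy(), bestv
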