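"""Low-level alignment kernels.

Numba-compiled unit-cost edit-distance primitives used throughout the
package:

* ``levenshtein`` — plain two-row dynamic programming, global distance.
* ``semiglobal_end_scores`` — Hyyrö/Myers blocked bit-parallel algorithm
  computing, for every text position j, the minimum edit distance of the
  whole pattern against any substring of the text ending at j (infix /
  semi-global search).  O(n * ceil(m/64)) words of work.

Sequences are passed as uint8 arrays with the 2-bit alphabet encoding
A=0, C=1, G=2, T=3 and N=4 (N never matches anything, including N).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGTN string into the uint8 alphabet used by the kernels."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


@njit(cache=True)
def levenshtein(a, b):  # pragma: no cover - exercised via wrappers
    """Unit-cost global edit distance between two encoded sequences."""
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    prev = np.empty(m + 1, dtype=np.int64)
    cur = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):
        prev[j] = j
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = 0 if (ai == b[j - 1] and ai < 4) else 1
            c = prev[j - 1] + cost
            if prev[j] + 1 < c:
                c = prev[j] + 1
            if cur[j - 1] + 1 < c:
                c = cur[j - 1] + 1
            cur[j] = c
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _build_peq(pattern, nblocks):
    # Bit mask per (symbol, block): bit r set iff pattern[64*b + r] == symbol.
    # N (code 4) matches nothing, so its row stays zero and N in the
    # pattern sets no bits.
    peq = np.zeros((5, nblocks), dtype=np.uint64)
    for i in range(len(pattern)):
        c = pattern[i]
        if c < 4:
            peq[c, i >> 6] |= np.uint64(1) << np.uint64(i & 63)
    return peq


@njit(cache=True)
def _myers_end_scores(pattern, text, prefix_mode):  # pragma: no cover
    """Blocked Myers/Hyyrö bit-vector scan; scores of pattern vs text prefixes.

    infix mode (prefix_mode=False): d[j] = min_i editdist(pattern, text[i:j+1])
    (top DP row all zeros — free start in the text).
    prefix mode (prefix_mode=True): d[j] = editdist(pattern, text[0:j+1])
    (top DP row 0..j — the alignment must start at text position 0).
    """
    m = len(pattern)
    n = len(text)
    out = np.empty(n, dtype=np.int32)
    if m == 0:
        for j in range(n):
            out[j] = (j + 1) if prefix_mode else 0
        return out
    nblocks = (m + 63) >> 6
    peq = _build_peq(pattern, nblocks)
    vp = np.empty(nblocks, dtype=np.uint64)
    vn = np.zeros(nblocks, dtype=np.uint64)
    for b in range(nblocks):
        vp[b] = np.uint64(0xFFFFFFFFFFFFFFFF)
    last_bit = np.uint64(1) << np.uint64((m - 1) & 63)
    one = np.uint64(1)
    score = m
    for j in range(n):
        c = text[j]
        hin = 1 if prefix_mode else 0
        for b in range(nblocks):
            eq = peq[c, b] if c < 4 else np.uint64(0)
            pv = vp[b]
            mv = vn[b]
            xv = eq | mv
            if hin < 0:
                eq |= one
            xh = (((eq & pv) + pv) ^ pv) | eq
            ph = mv | ~(xh | pv)
            mh = pv & xh
            hout = 0
            msb = last_bit if b == nblocks - 1 else (one << np.uint64(63))
            if ph & msb:
                hout = 1
            elif mh & msb:
                hout = -1
            ph = ph << one
            mh = mh << one
            if hin < 0:
                mh |= one
            elif hin > 0:
                ph |= one
            vp[b] = mh | ~(xv | ph)
            vn[b] = ph & xv
            hin = hout
        score += hin
        out[j] = score
    return out


def semiglobal_end_scores(pattern, text):
    """Infix scan: ``d[j] = min_i editdist(pattern, text[i:j+1])``."""
    return _myers_end_scores(pattern, text, False)


@njit(cache=True)
def prefix_diag_scores(a, b):  # pragma: no cover
    """d[t] = editdist(a[:t], b[:t]) for t = 0..min(len(a), len(b)).

    The diagonal of the full DP matrix; used to find how far two sequences
    stay homologous from a shared anchor point (e.g. locating the edge of
    a tandem array against its own periodic extension).
    """
    n = min(len(a), len(b))
    prev = np.arange(n + 1).astype(np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    diag = np.empty(n + 1, dtype=np.int32)
    diag[0] = 0
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, n + 1):
            cost = 0 if (ai == b[j - 1] and ai < 4) else 1
            c = prev[j - 1] + cost
            if prev[j] + 1 < c:
                c = prev[j] + 1
            if cur[j - 1] + 1 < c:
                c = cur[j - 1] + 1
            cur[j] = c
        diag[i] = cur[i]
        prev, cur = cur, prev
    return diag


def edit_distance(a, b) -> int:
    """Global unit-cost edit distance via the bit-parallel kernel.

    Prefix-anchored scores of ``a`` against the whole of ``b``; the final
    entry is the global distance.  O(n * ceil(m/64)) instead of O(n*m).
    """
    if len(a) == 0 or len(b) == 0:
        return len(a) + len(b)
    return int(_myers_end_scores(a, b, True)[-1])


@njit(cache=True)
def semiglobal_best_start(pattern, text, end):  # pragma: no cover
    """Start position of the best alignment of ``pattern`` ending at ``end``.

    Runs the prefix-anchored recurrence on the reversed pair (the end is
    fixed, the start is scanned); ties prefer the shortest span.  Returns
    (start, score).
    """
    rp = pattern[::-1].copy()
    lo = end + 1 - min(end + 1, len(pattern) * 2 + 64)
    rt = text[lo : end + 1][::-1].copy()
    sc = _myers_end_scores(rp, rt, True)
    best = sc[0]
    bestj = 0
    for j in range(1, len(sc)):
        if sc[j] < best:
            best = sc[j]
            bestj = j
    return end - bestj, best
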