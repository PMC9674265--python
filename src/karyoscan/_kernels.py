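"""Numba Smith-Waterman kernel shared by the similarity-search module.

Scoring is linear-gap: MATCH=+1, MISMATCH=-2, GAP=-3. N (code 4) never
matches anything, including another N. Tie-breaking is fully deterministic:
among equal-scoring end cells the one with the smaller subject coordinate,
then the smaller query coordinate, wins; traceback prefers diagonal over
up (gap in subject) over left (gap in query).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP = -3

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0 C=1 G=2 T=3, other=N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_align(q, s):  # pragma: no cover - exercised via local_search
    """Best local alignment of encoded query q against subject s.

    Returns (score, q_start, q_end, s_start, s_end, matches, columns).
    Intervals are 0-based half-open. score == 0 means no positive-scoring
    alignment exists.
    """
    m = q.shape[0]
    n = s.shape[0]
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    prev = np.zeros(n + 1, dtype=np.int32)
    cur = np.zeros(n + 1, dtype=np.int32)

    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            if qi == s[j - 1] and qi != 4:
                diag = prev[j - 1] + MATCH
            else:
                diag = prev[j - 1] + MISMATCH
            up = prev[j] + GAP
            left = cur[j - 1] + GAP
            h = diag
            p = 1
            if up > h:
                h = up
                p = 2
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            cur[j] = h
            ptr[i, j] = p
            if h > best or (h == best and h > 0 and
                            (j < best_j or (j == best_j and i < best_i))):
                best = h
                best_i = i
                best_j = j
        tmp = prev
        prev = cur
        cur = tmp
        cur[:] = 0

    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback from (best_i, best_j)
    i = best_i
    j = best_j
    matches = 0
    columns = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        columns += 1
        if p == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, i, best_i, j, best_j, matches, columns


@njit(cache=True)
def sw_align_banded(q, s, dlo, dhi):  # pragma: no cover - via local_search
    """Local alignment restricted to diagonals j - i in [dlo, dhi].

    Same scoring and tie-breaking as :func:`sw_align`; cells outside the band
    are unreachable. Returns the same tuple.
    """
    m = q.shape[0]
    n = s.shape[0]
    w = dhi - dlo + 1
    ptr = np.zeros((m + 1, w), dtype=np.uint8)
    prev = np.full(w, -1_000_000, dtype=np.int32)
    cur = np.full(w, -1_000_000, dtype=np.int32)

    # row 0: cells (0, j) with j = dlo + b, score 0 where 0 <= j <= n
    for b in range(w):
        j = dlo + b
        if 0 <= j <= n:
            prev[b] = 0

    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for b in range(w):
            j = i + dlo + b
            if j < 1 or j > n:
                cur[b] = -1_000_000 if j != 0 else 0
                if j == 0:
                    cur[b] = 0
                ptr[i, b] = 0
                continue
            # diag: (i-1, j-1) -> same band index b
            diag = prev[b]
            if qi == s[j - 1] and qi != 4:
                diag += MATCH
            else:
                diag += MISMATCH
            # up: (i-1, j) -> band index b+1 in row i-1
            up = prev[b + 1] + GAP if b + 1 < w else -1_000_000
            # left: (i, j-1) -> band index b-1 in row i
            left = cur[b - 1] + GAP if b >= 1 else -1_000_000
            h = diag
            p = 1
            if up > h:
                h = up
                p = 2
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            cur[b] = h
            ptr[i, b] = p
            if h > best or (h == best and h > 0 and
                            (j < best_j or (j == best_j and i < best_i))):
                best = h
                best_i = i
                best_j = j
        tmp = prev
        prev = cur
        cur = tmp

    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0

    i = best_i
    j = best_j
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        b = j - i - dlo
        if b < 0 or b >= w or ptr[i, b] == 0:
            break
        p = ptr[i, b]
        columns += 1
        if p == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, i, best_i, j, best_j, matches, columns
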