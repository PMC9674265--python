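"""Independent brute-force oracles used to check the package's fast paths.

These deliberately re-derive results from first principles (full-matrix
dynamic programming, per-base counting, all-pairs loops) and share no code
with the implementation they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from numba import njit

# scoring contract of the similarity-search module, restated literally
MATCH = 1
MISMATCH = -2
GAP = -3


@njit(cache=True)
def _sw_full(q, s):
    """Exhaustive full-matrix Smith-Waterman.

    Tie-breaking mirrors the documented contract: among equal best scores
    the cell with the smaller subject coordinate, then the smaller query
    coordinate, wins; traceback prefers diagonal, then up, then left.
    """
    m, n = q.shape[0], s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = MATCH if (q[i - 1] == s[j - 1] and q[i - 1] != 4) else MISMATCH
            h = H[i - 1, j - 1] + sub
            if H[i - 1, j] + GAP > h:
                h = H[i - 1, j] + GAP
            if H[i, j - 1] + GAP > h:
                h = H[i, j - 1] + GAP
            if h < 0:
                h = 0
            H[i, j] = h
    best = 0
    bi = 0
    bj = 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i, j] > best or (H[i, j] == best and H[i, j] > 0 and
                                  (j < bj or (j == bj and i < bi))):
                best = H[i, j]
                bi, bj = i, j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    i, j = bi, bj
    matches = 0
    columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = MATCH if (q[i - 1] == s[j - 1] and q[i - 1] != 4) else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + sub:
            if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, i, bi, j, bj, matches, columns


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def sw_oracle(query: str, subject: str):
    """(score, q_start, q_end, s_start, s_end, identity_pct, aln_length)."""
    q = np.array([_CODE.get(c, 4) for c in query.upper()], dtype=np.uint8)
    s = np.array([_CODE.get(c, 4) for c in subject.upper()], dtype=np.uint8)
    score, qs, qe, ss, se, matches, columns = _sw_full(q, s)
    ident = 100.0 * matches / columns if columns else 0.0
    return score, qs, qe, ss, se, ident, columns


def density_oracle(intervals, contig_length, window, step):
    """Per-base brute-force windowed coverage fractions for one contig."""
    covered = np.zeros(contig_length, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    rows = []
    start = 0
    while start < contig_length:
        end = min(start + window, contig_length)
        rows.append((start, end, covered[start:end].sum() / (end - start)))
        if end == contig_length:
            break
        start += step
    return rows


def pi_oracle(haplotypes, length):
    """Average pairwise differences per site, all-pairs loop."""
    total = 0
    pairs = 0
    for a, b in combinations(haplotypes, 2):
        total += sum(1 for x, y in zip(a, b) if x != y)
        pairs += 1
    return total / (pairs * length)


def matrix_pi_oracle(genotypes, callable_length):
    """pi from a site x sample int matrix with -1 missing."""
    n = genotypes.shape[1]
    total = 0
    pairs = 0
    for i, j in combinations(range(n), 2):
        pairs += 1
        for k in range(genotypes.shape[0]):
            a, b = genotypes[k, i], genotypes[k, j]
            if a != -1 and b != -1 and a != b:
                total += 1
    return total / (pairs * callable_length)


def site_frequency_oracle(records):
    """Per-(contig, pos) methylation tallies from an iterable of
    (contig, pos, methylated) tuples."""
    tally = {}
    for contig, pos, methylated in records:
        key = (contig, pos)
        m, t = tally.get(key, (0, 0))
        tally[key] = (m + int(methylated), t + 1)
    return {k: m / t for k, (m, t) in tally.items()}
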