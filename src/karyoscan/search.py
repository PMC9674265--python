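"""Self-contained local similarity search.

Seed-and-extend over exact k-mer anchors (default k=15) with a windowed
Smith-Waterman extension, plus an exhaustive-DP fallback for short queries
when no anchors are found. Identity is matches / alignment columns, so gaps
count against identity; both strands are always searched and results are
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .genome import AnnotationRecord, Genome, revcomp

DEFAULT_SEED_K = 15
_DIAG_BAND = 100       # anchors within this diagonal spread extend together
_WINDOW_MARGIN = 150   # subject window padding around the projected query span
_DP_FALLBACK_MAX_Q = 2_000
_DP_FALLBACK_MAX_S = 120_000


class SearchError(ValueError):
    """Raised on invalid similarity-search input."""


@dataclass(frozen=True)
class SimilarityHit:
    """One local alignment between a query and a subject contig.

    Coordinates are 0-based half-open; query coordinates always refer to the
    forward orientation of the query, with ``strand`` recording which subject
    strand the query matched.
    """

    query_id: str
    subject_contig: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    pct_identity: float
    aln_length: int
    matches: int
    score: int

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("hit intervals must be non-empty")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity out of [0, 100]")


class KmerIndex:
    """Exact k-mer index over a genome, reusable across many queries."""

    def __init__(self, genome: Genome, k: int = DEFAULT_SEED_K):
        self.genome = genome
        self.k = k
        self._index: dict[str, dict[str, list[int]]] = {}
        self.encoded: dict[str, "np.ndarray"] = {}
        for contig, seq in genome.contigs.items():
            self.encoded[contig] = _kernels.encode(seq)
            d: dict[str, list[int]] = {}
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                d.setdefault(kmer, []).append(pos)
            self._index[contig] = d

    def lookup(self, kmer: str, contig: str) -> list[int]:
        return self._index[contig].get(kmer, [])


def _extend_cluster(query_enc, subject_enc, contig, query_id, strand, qlen,
                    dlo, dhi):
    res = _kernels.sw_align_banded(query_enc, subject_enc,
                                   dlo - _WINDOW_MARGIN, dhi + _WINDOW_MARGIN)
    score, qs, qe, ss, se, matches, columns = res
    if score <= 0 or columns == 0:
        return None
    if strand == "-":
        q_start, q_end = qlen - qe, qlen - qs
    else:
        q_start, q_end = qs, qe
    return SimilarityHit(
        query_id=query_id, subject_contig=contig,
        q_start=q_start, q_end=q_end, s_start=ss, s_end=se,
        strand=strand, pct_identity=100.0 * matches / columns,
        aln_length=columns, matches=matches, score=score)


def _cluster_anchors(anchors: list[tuple[int, int]], qlen: int
                     ) -> list[tuple[int, int]]:
    """Group (diag, s_pos) anchors into diagonal ranges to extend over.

    Isolated anchors on long queries are almost always chance k-mer
    collisions; a genuine hit long enough to matter seeds many anchors, so
    sparse clusters are not extended.
    """
    min_anchors = 3 if qlen >= 200 else 1
    ranges: list[tuple[int, int]] = []
    anchors.sort()
    group: list[tuple[int, int]] = []

    def flush(g: list[tuple[int, int]]) -> None:
        if len(g) < min_anchors:
            return
        ranges.append((g[0][0], g[-1][0]))   # anchors sorted by diag

    for diag, spos in anchors:
        if group and diag - group[-1][0] > _DIAG_BAND:
            flush(group)
            group = []
        group.append((diag, spos))
    flush(group)
    return ranges


def _dedup(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Drop hits whose subject interval is mostly contained in a better hit."""
    hits = sorted(hits, key=lambda h: (-h.score, h.subject_contig, h.s_start,
                                       h.strand))
    kept: list[SimilarityHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if k.subject_contig != h.subject_contig or k.strand != h.strand:
                continue
            ov = min(k.s_end, h.s_end) - max(k.s_start, h.s_start)
            if ov > 0.5 * (h.s_end - h.s_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def local_search(
    query_seq: str,
    subject: Genome,
    min_identity: float = 0.0,
    min_length: int = 1,
    seed_k: int = DEFAULT_SEED_K,
    index: KmerIndex | None = None,
    query_id: str = "query",
) -> list[SimilarityHit]:
    """All maximal local alignments of ``query_seq`` against ``subject``.

    Hits passing (``min_identity`` percent, ``min_length`` alignment columns)
    come back sorted by descending score, ties broken by leftmost subject
    coordinate. Both strands are searched.
    """
    if len(query_seq) < seed_k:
        raise SearchError(
            f"query length {len(query_seq)} shorter than seed_k={seed_k}")
    query_seq = query_seq.upper()
    if index is not None and index.k != seed_k:
        raise SearchError("supplied index was built with a different seed_k")
    if index is None:
        index = KmerIndex(subject, seed_k)

    hits: list[SimilarityHit] = []
    qlen = len(query_seq)
    for strand, q in (("+", query_seq), ("-", revcomp(query_seq))):
        q_enc = _kernels.encode(q)
        for contig, seq in subject.contigs.items():
            s_enc = index.encoded[contig]
            anchors: list[tuple[int, int]] = []
            for qpos in range(0, qlen - seed_k + 1):
                kmer = q[qpos:qpos + seed_k]
                if "N" in kmer:
                    continue
                for spos in index.lookup(kmer, contig):
                    anchors.append((spos - qpos, spos))
            clusters = _cluster_anchors(anchors, qlen) if anchors else []
            if clusters:
                for dlo, dhi in clusters:
                    hit = _extend_cluster(q_enc, s_enc, contig, query_id,
                                          strand, qlen, dlo, dhi)
                    if hit is not None:
                        hits.append(hit)
            elif (qlen <= _DP_FALLBACK_MAX_Q and len(seq) <= _DP_FALLBACK_MAX_S):
                res = _kernels.sw_align(q_enc, s_enc)
                score, qs, qe, ss, se, matches, columns = res
                if score > 0 and columns > 0:
                    if strand == "-":
                        q_start, q_end = qlen - qe, qlen - qs
                    else:
                        q_start, q_end = qs, qe
                    hits.append(SimilarityHit(
                        query_id=query_id, subject_contig=contig,
                        q_start=q_start, q_end=q_end, s_start=ss, s_end=se,
                        strand=strand, pct_identity=100.0 * matches / columns,
                        aln_length=columns, matches=matches, score=score))

    hits = _dedup(hits)
    hits = [h for h in hits
            if h.pct_identity >= min_identity and h.aln_length >= min_length]
    hits.sort(key=lambda h: (-h.score, h.subject_contig, h.s_start, h.strand))
    return hits


def hits_to_table(hits: Iterable[SimilarityHit]) -> pd.DataFrame:
    """Tabular (blast-outfmt6-like) view of a hit list."""
    rows = []
    for h in hits:
        rows.append({
            "query": h.query_id,
            "subject": h.subject_contig,
            "pident": round(h.pct_identity, 3),
            "length": h.aln_length,
            "mismatch": h.aln_length - h.matches,
            "gapopen": max(0, h.aln_length - (h.q_end - h.q_start)),
            "qstart": h.q_start,
            "qend": h.q_end,
            "sstart": h.s_start if h.strand == "+" else h.s_end,
            "send": h.s_end if h.strand == "+" else h.s_start,
            "evalue": ".",
            "bitscore": h.score,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Terminal inverted repeats
# ---------------------------------------------------------------------------

def self_inverted_repeat(
    seq: str,
    min_tir_len: int = 10,
    min_tir_identity: float = 80.0,
) -> tuple[int, float] | None:
    """Terminal inverted repeat found by aligning a sequence to its own
    reverse complement.

    The 5' end is compared, ungapped, against the reverse complement of the
    3' end; the reported TIR is the maximal-scoring terminal segment
    (match +1 / mismatch -1, ties resolved toward the longer segment).
    Returns (tir_length, percent identity) or None if no segment of at least
    ``min_tir_len`` reaches ``min_tir_identity``.
    """
    seq = seq.upper()
    if len(seq) < 2 * min_tir_len:
        return None
    rc = revcomp(seq)
    half = len(seq) // 2
    best_k = 0
    best_score = 0
    best_matches = 0
    score = 0
    matches = 0
    for i in range(half):
        if seq[i] == rc[i] and seq[i] != "N":
            score += 1
            matches += 1
        else:
            score -= 1
        k = i + 1
        if k >= min_tir_len and score >= best_score:
            best_score = score
            best_k = k
            best_matches = matches
    if best_k < min_tir_len:
        return None
    identity = 100.0 * best_matches / best_k
    if identity < min_tir_identity:
        return None
    return best_k, identity


# ---------------------------------------------------------------------------
# Source-copy attribution
# ---------------------------------------------------------------------------

@dataclass
class SourceAttribution:
    copy_ids: list[str]       # all top candidates (>1 means ambiguous tie)
    pct_identity: float
    ambiguous: bool


def best_source_copy(
    new_insertion_seq: str,
    candidate_copies: Sequence[tuple[AnnotationRecord, str]],
) -> SourceAttribution:
    """Attribute a new insertion to the candidate copy with maximal identity.

    Candidates are (annotation, sequence) pairs. Exact identity ties are
    reported as an ambiguous set rather than resolved arbitrarily.
    """
    if not candidate_copies:
        raise SearchError("no candidate copies supplied")
    q_enc = _kernels.encode(new_insertion_seq.upper())
    scored: list[tuple[float, str]] = []
    for rec, seq in candidate_copies:
        best_score = -1
        best_ident = 0.0
        for s in (seq.upper(), revcomp(seq.upper())):
            res = _kernels.sw_align(q_enc, _kernels.encode(s))
            score, _, _, _, _, matches, columns = res
            if columns > 0 and score > best_score:
                best_score = score
                best_ident = 100.0 * matches / columns
        scored.append((best_ident, rec.copy_id))
    top = max(ident for ident, _ in scored)
    winners = [cid for ident, cid in scored if abs(ident - top) < 1e-9]
    return SourceAttribution(sorted(winners), top, ambiguous=len(winners) > 1)
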