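"""Flank-anchored TE presence/absence calling between genome assemblies.

For every sufficiently long annotated TE copy in a donor assembly, the 5' and
3' flanks are extracted and searched against a target assembly. A locus where
both flank hits land next to each other (the TE is gone) is a putative empty
site; it is confirmed by re-searching the merged flank sequence and requiring
a single long, near-identical hit. Homologous loci found in several pairwise
comparisons are clustered, and target-site duplications are detected at the
junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import AnnotationRecord, Genome
from .search import KmerIndex, SimilarityHit, local_search

logger = logging.getLogger(__name__)

FLANK_LEN = 5_000
MIN_TE_LEN = 120
MAX_GAP = 20
MIN_FLANK_ALN = 4_500
CONFIRM_MIN_IDENTITY = 99.0
CONFIRM_MIN_LEN = 9_000
MAX_LOCUS_SPAN = 70_000


def implied_max_insertion_size(
    max_locus_span: int = MAX_LOCUS_SPAN,
    min_confirm_len: int = CONFIRM_MIN_LEN,
) -> int:
    """Largest insertion the locus-span rule can accommodate.

    With homologous flanks at most ``max_locus_span`` apart and the confirmed
    empty locus occupying ``min_confirm_len`` of that, an insertion cannot
    exceed ``max_locus_span - min_confirm_len`` (61 kb at the defaults).
    """
    return max_locus_span - min_confirm_len


@dataclass
class FlankPair:
    """5' and 3' flanks of one TE copy, excluding the TE itself."""

    te_copy_id: str
    family_id: str
    left_flank: str
    right_flank: str
    genome_id: str
    contig: str
    te_start: int
    te_end: int
    flank_len: int
    left_truncated: bool = False
    right_truncated: bool = False
    nested: bool = False   # flank overlaps another annotation
    tandem: bool = False   # same-family copy within 50 bp


@dataclass
class EmptySiteCall:
    te_copy_id: str
    family_id: str
    donor_genome: str
    target_genome: str
    target_contig: str
    junction_position: int
    strand: str
    status: str                        # "putative" | "confirmed"
    left_hit: SimilarityHit | None = None
    right_hit: SimilarityHit | None = None
    merged_hit: SimilarityHit | None = None
    tsd: str | None = None
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("putative", "confirmed"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "confirmed" and self.merged_hit is None:
            raise ValueError("confirmed call requires a merged hit")


@dataclass
class LocusCluster:
    members: list[EmptySiteCall]
    representative: dict[str, tuple[str, int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

def extract_flanks(
    genome: Genome,
    annotations: Sequence[AnnotationRecord],
    flank_len: int = FLANK_LEN,
    min_te_len: int = MIN_TE_LEN,
) -> list[FlankPair]:
    """One flank pair per annotated TE strictly longer than ``min_te_len``.

    Flanks are truncated at contig ends (flagged); flanks overlapping another
    annotation are flagged nested but still processed, and same-family copies
    within 50 bp are flagged tandem.
    """
    pairs: list[FlankPair] = []
    by_contig: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        by_contig.setdefault(rec.contig, []).append(rec)

    for rec in annotations:
        if rec.length <= min_te_len:
            continue
        seq = genome.contigs[rec.contig]
        lstart = max(0, rec.start - flank_len)
        rend = min(len(seq), rec.end + flank_len)
        neighbours = [o for o in by_contig[rec.contig] if o.copy_id != rec.copy_id]
        nested = any(o.start < rec.end + flank_len and o.end > rec.start - flank_len
                     for o in neighbours)
        tandem = any(o.family_id == rec.family_id
                     and (abs(o.start - rec.end) <= 50 or abs(rec.start - o.end) <= 50)
                     for o in neighbours)
        pairs.append(FlankPair(
            te_copy_id=rec.copy_id,
            family_id=rec.family_id,
            left_flank=seq[lstart:rec.start],
            right_flank=seq[rec.end:rend],
            genome_id=genome.id,
            contig=rec.contig,
            te_start=rec.start,
            te_end=rec.end,
            flank_len=flank_len,
            left_truncated=rec.start - lstart < flank_len,
            right_truncated=rend - rec.end < flank_len,
            nested=nested,
            tandem=tandem,
        ))
    return pairs


# ---------------------------------------------------------------------------
# Putative and confirmed empty sites
# ---------------------------------------------------------------------------

def _best_hit(hits: list[SimilarityHit]) -> SimilarityHit | None:
    return hits[0] if hits else None


def call_putative_empty_site(
    flankpair: FlankPair,
    subject: Genome,
    max_gap: int = MAX_GAP,
    min_flank_aln: int = MIN_FLANK_ALN,
    index: KmerIndex | None = None,
) -> EmptySiteCall | None:
    """Putative empty site from the best hits of the two flanks.

    A call is made iff the best left- and right-flank hits are on the same
    subject contig, in the same orientation, with an inner gap between them of
    at most ``max_gap`` bp (small overlaps down to -``max_gap`` are allowed:
    deletion breakpoints may chew into the junction). Loci whose flanks are
    too short to ever reach ``min_flank_aln`` are skipped with a logged
    reason.
    """
    if (len(flankpair.left_flank) < min_flank_aln
            or len(flankpair.right_flank) < min_flank_aln):
        logger.info("skipping %s: truncated flank shorter than %d bp",
                    flankpair.te_copy_id, min_flank_aln)
        return None

    left = _best_hit(local_search(
        flankpair.left_flank, subject, min_identity=80.0,
        min_length=min_flank_aln, index=index,
        query_id=f"{flankpair.te_copy_id}|L"))
    right = _best_hit(local_search(
        flankpair.right_flank, subject, min_identity=80.0,
        min_length=min_flank_aln, index=index,
        query_id=f"{flankpair.te_copy_id}|R"))
    if left is None or right is None:
        return None
    if left.subject_contig != right.subject_contig or left.strand != right.strand:
        return None
    if left.strand == "+":
        gap = right.s_start - left.s_end
        junction = (left.s_end + right.s_start) // 2
    else:
        gap = left.s_start - right.s_end
        junction = (right.s_end + left.s_start) // 2
    if not (-max_gap <= gap <= max_gap):
        return None
    return EmptySiteCall(
        te_copy_id=flankpair.te_copy_id,
        family_id=flankpair.family_id,
        donor_genome=flankpair.genome_id,
        target_genome=subject.id,
        target_contig=left.subject_contig,
        junction_position=junction,
        strand=left.strand,
        status="putative",
        left_hit=left,
        right_hit=right,
    )


def confirm_empty_site(
    call: EmptySiteCall,
    flankpair: FlankPair,
    subject: Genome,
    min_identity: float = CONFIRM_MIN_IDENTITY,
    min_len: int = CONFIRM_MIN_LEN,
    index: KmerIndex | None = None,
) -> EmptySiteCall:
    """Confirm a putative call by re-searching the merged flank sequence.

    The merged left+right flank must produce exactly one hit with at least
    ``min_identity`` percent identity over at least ``min_len`` alignment
    columns; otherwise the call stays putative with the rejection recorded.
    """
    if call.status != "putative":
        raise ValueError("confirm_empty_site expects a putative call")
    merged = flankpair.left_flank + flankpair.right_flank
    hits = local_search(merged, subject, min_identity=min_identity,
                        min_length=min_len, index=index,
                        query_id=f"{flankpair.te_copy_id}|merged")
    if len(hits) == 1:
        call.status = "confirmed"
        call.merged_hit = hits[0]
    elif len(hits) == 0:
        call.rejection_reason = "no merged-flank hit passing thresholds"
    else:
        call.rejection_reason = f"{len(hits)} merged-flank hits (single-hit rule)"
    return call


# ---------------------------------------------------------------------------
# Target-site duplications
# ---------------------------------------------------------------------------

def detect_tsd(
    filled_seq: str,
    empty_seq: str,
    max_tsd: int = 20,
) -> tuple[str, bool] | None:
    """Longest exact target-site duplication at an insertion junction.

    ``filled_seq`` and ``empty_seq`` are homologous locus sequences with and
    without the insertion. The insertion is located from the longest common
    prefix/suffix of the two; the TSD is the longest word of up to
    ``max_tsd`` bp that ends the insertion and also immediately precedes the
    junction (i.e. flanks the insertion on both sides in the filled locus but
    appears once in the empty one). Returns (tsd, ambiguous) or None; the
    ambiguity flag is set when the junction placement itself is not unique
    (e.g. homopolymer junctions).
    """
    filled_seq = filled_seq.upper()
    empty_seq = empty_seq.upper()
    m = len(filled_seq) - len(empty_seq)
    if m <= 0:
        return None
    # longest common prefix / suffix
    lcp = 0
    limit = len(empty_seq)
    while lcp < limit and filled_seq[lcp] == empty_seq[lcp]:
        lcp += 1
    lcs = 0
    while lcs < limit - 0 and filled_seq[len(filled_seq) - 1 - lcs] == \
            empty_seq[len(empty_seq) - 1 - lcs]:
        lcs += 1
        if lcs >= limit:
            break
    ambiguous = lcp + lcs > len(empty_seq)
    insert = filled_seq[lcp:lcp + m]
    best: str | None = None
    for t in range(1, min(max_tsd, lcp, m) + 1):
        if filled_seq[lcp - t:lcp] == insert[m - t:]:
            best = insert[m - t:]
    if best is None:
        return None
    return best, ambiguous


# ---------------------------------------------------------------------------
# Clustering homologous loci
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _flanks_homologous(a: FlankPair, b: FlankPair,
                       min_identity: float, min_len: int) -> bool:
    for qa, qb in ((a.left_flank, b.left_flank), (a.right_flank, b.right_flank)):
        if len(qa) < 15 or len(qb) < 15:
            continue
        subject = Genome("flank", {"f": qb})
        if local_search(qa, subject, min_identity=min_identity,
                        min_length=min(min_len, len(qa), len(qb))):
            return True
    return False


def cluster_homologous_loci(
    calls: Sequence[EmptySiteCall],
    flankpairs: Mapping[tuple[str, str], FlankPair],
    max_locus_span: int = MAX_LOCUS_SPAN,
    homology_min_identity: float = 95.0,
    homology_min_len: int = 1_000,
) -> list[LocusCluster]:
    """Group pairwise empty-site calls that describe the same locus.

    Calls are linked when their donor flanks are reciprocally homologous
    (including trivially, via a shared donor copy). Groups whose calls in any
    one genome lie more than ``max_locus_span`` apart are split: homologous
    flanks cannot be farther from each other than that.
    """
    if not calls:
        return []
    n = len(calls)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.te_copy_id == b.te_copy_id and a.donor_genome == b.donor_genome:
                uf.union(i, j)
                continue
            fa = flankpairs.get((a.donor_genome, a.te_copy_id))
            fb = flankpairs.get((b.donor_genome, b.te_copy_id))
            if fa is None or fb is None:
                continue
            if _flanks_homologous(fa, fb, homology_min_identity, homology_min_len):
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters: list[LocusCluster] = []
    for idxs in groups.values():
        # enforce the per-genome span cap by splitting at oversized gaps
        members = [calls[i] for i in idxs]
        members.sort(key=lambda c: (c.target_genome, c.target_contig,
                                    c.junction_position))
        parts: list[list[EmptySiteCall]] = [[members[0]]]
        for prev, cur in zip(members, members[1:]):
            same_locus_frame = (prev.target_genome == cur.target_genome
                                and prev.target_contig == cur.target_contig)
            if same_locus_frame and \
                    cur.junction_position - prev.junction_position > max_locus_span:
                parts.append([cur])
            else:
                parts[-1].append(cur)
        for part in parts:
            rep: dict[str, tuple[str, int, int]] = {}
            for c in part:
                key = c.target_genome
                if key in rep:
                    ctg, lo, hi = rep[key]
                    rep[key] = (ctg, min(lo, c.junction_position),
                                max(hi, c.junction_position))
                else:
                    rep[key] = (c.target_contig, c.junction_position,
                                c.junction_position)
            clusters.append(LocusCluster(part, rep))
    return clusters


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

def scan_empty_sites(
    donor: Genome,
    donor_annotations: Sequence[AnnotationRecord],
    target: Genome,
    flank_len: int = FLANK_LEN,
    min_te_len: int = MIN_TE_LEN,
    max_gap: int = MAX_GAP,
    min_flank_aln: int = MIN_FLANK_ALN,
    confirm_identity: float = CONFIRM_MIN_IDENTITY,
    confirm_len: int = CONFIRM_MIN_LEN,
    index: KmerIndex | None = None,
    detect_tsds: bool = True,
    max_tsd: int = 20,
) -> list[EmptySiteCall]:
    """Run the full donor-vs-target empty-site scan for one genome pair."""
    if index is None:
        index = KmerIndex(target)
    calls: list[EmptySiteCall] = []
    for fp in extract_flanks(donor, donor_annotations, flank_len, min_te_len):
        call = call_putative_empty_site(fp, target, max_gap, min_flank_aln, index)
        if call is None:
            continue
        call = confirm_empty_site(call, fp, target, confirm_identity,
                                  confirm_len, index)
        if call.status == "confirmed" and detect_tsds:
            # duplication flanking the TE in the filled (donor) locus ...
            best = None
            for t in range(1, max_tsd + 1):
                if (t <= len(fp.left_flank) and t <= len(fp.right_flank)
                        and fp.left_flank[-t:] == fp.right_flank[:t]):
                    best = fp.right_flank[:t]
            # ... that also appears at the empty junction in the target
            if best is not None:
                j = call.junction_position
                tseq = target.contigs[call.target_contig]
                window = tseq[max(0, j - max_tsd - len(best)):
                              j + max_tsd + len(best)]
                if best in window:
                    call.tsd = best
        calls.append(call)
    return calls


def calls_to_frame(calls: Iterable[EmptySiteCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "te_copy_id": c.te_copy_id,
            "family_id": c.family_id,
            "donor_genome": c.donor_genome,
            "target_genome": c.target_genome,
            "target_contig": c.target_contig,
            "junction": c.junction_position,
            "strand": c.strand,
            "status": c.status,
            "merged_identity": (round(c.merged_hit.pct_identity, 3)
                                if c.merged_hit else float("nan")),
            "merged_length": (c.merged_hit.aln_length if c.merged_hit else 0),
            "tsd": c.tsd or ".",
            "rejection_reason": c.rejection_reason or ".",
        })
    return pd.DataFrame(rows)
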