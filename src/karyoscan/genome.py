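"""Genome containers, annotation I/O, windowed density tracks and contig joining.

Internal coordinates are 0-based half-open everywhere; conversion between
conventions happens only at I/O boundaries (RepeatMasker tables are 1-based
inclusive, BED is already 0-based half-open).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


class AnnotationError(ValueError):
    """Raised on malformed or inconsistent annotation input."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_RC)[::-1]


@dataclass
class Genome:
    """A named assembly: ordered map of contig name -> DNA string (upper case)."""

    id: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"contig {name!r} has invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.contigs)

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])

    def slice(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated TE copy (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    copy_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.copy_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.copy_id}: strand must be + or -")
        if not self.family_id:
            raise AnnotationError(f"{self.copy_id}: empty family_id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DensityTrack:
    """Per-window fraction of bases covered by annotations."""

    windows: list[tuple[str, int, int, float]]
    window_size: int
    step: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, start, end, frac in self.windows:
                fh.write(f"{contig}\t{start}\t{end}\t{frac:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, genome_id: str | None = None) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Sequences are upper-cased; the alphabet is restricted to A/C/G/T/N.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise FastaParseError(f"{path}: duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: contig {rec.id!r} has no sequence")
        bad = set(seq) - _VALID
        if bad:
            raise FastaParseError(
                f"{path}: contig {rec.id!r} has invalid characters {sorted(bad)}")
        contigs[rec.id] = seq
    return Genome(id=genome_id or path.stem, contigs=contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_RM_HEADER = re.compile(r"^\s*(SW|score|$)")


def read_annotations(
    path: str | Path,
    dialect: str = "bed",
    genome: Genome | None = None,
) -> list[AnnotationRecord]:
    """Read TE annotations from BED6 or a RepeatMasker ``.out``-style table.

    RepeatMasker coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is taken as-is. Records come back sorted
    by (contig, start). When ``genome`` is supplied, intervals are validated
    against contig lengths.
    """
    if dialect not in ("bed", "repeatmasker_out"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[AnnotationRecord] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if dialect == "bed":
                if line.startswith(("track", "browser", "#")):
                    continue
                f = line.split()
                if len(f) < 3:
                    raise AnnotationError(f"{path}:{lineno}: short BED line")
                contig, start, end = f[0], int(f[1]), int(f[2])
                family = f[3] if len(f) > 3 else "unknown"
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
                copy_id = f"{family}#{contig}:{start}"
            else:  # repeatmasker_out
                if _RM_HEADER.match(line):
                    continue
                f = line.split()
                if len(f) < 11:
                    raise AnnotationError(
                        f"{path}:{lineno}: short RepeatMasker line")
                # columns: score div del ins query qbegin qend qleft strand
                #          repeat class/family ...
                contig = f[4]
                start = int(f[5]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(f[6])
                strand = "-" if f[8] in ("C", "-") else "+"
                family = f[9]
                copy_id = f"{family}#{contig}:{start}"
            counter += 1
            if genome is not None:
                if contig not in genome.contigs:
                    raise AnnotationError(
                        f"{path}:{lineno}: unknown contig {contig!r}")
                if end > genome.contig_length(contig):
                    raise AnnotationError(
                        f"{path}:{lineno}: interval end {end} beyond contig "
                        f"{contig!r} length {genome.contig_length(contig)}")
            records.append(
                AnnotationRecord(contig, start, end, strand, family, copy_id))
    records.sort(key=lambda r: (r.contig, r.start, r.end))
    return records


def write_annotations_bed(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.family_id}\t.\t{r.strand}"
                     f"\t{r.copy_id}\n")


# ---------------------------------------------------------------------------
# Interval utilities and density
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def windowed_density(
    annotations: Sequence[AnnotationRecord],
    genome: Genome,
    window: int = 50_000,
    step: int = 10_000,
) -> DensityTrack:
    """Fraction of each sliding window covered by the union of annotations.

    Windows tile each contig from 0 at the given step; the trailing window is
    truncated at the contig end and its fraction uses the truncated length.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for r in annotations:
        if r.contig not in genome.contigs:
            raise AnnotationError(f"annotation contig {r.contig!r} not in genome")
        if r.end > genome.contig_length(r.contig):
            raise AnnotationError(f"annotation {r.copy_id} beyond contig end")
        by_contig.setdefault(r.contig, []).append((r.start, r.end))

    rows: list[tuple[str, int, int, float]] = []
    for contig, seq in genome.contigs.items():
        length = len(seq)
        merged = merge_intervals(by_contig.get(contig, []))
        starts = [s for s, _ in merged]
        # prefix[i] = covered bases in merged[:i]
        prefix = [0]
        for s, e in merged:
            prefix.append(prefix[-1] + (e - s))

        def covered(lo: int, hi: int) -> int:
            total = 0
            i = bisect_right(starts, lo) - 1
            if i >= 0:
                s, e = merged[i]
                if e > lo:
                    total += min(e, hi) - lo
                i += 1
            else:
                i = 0
            while i < len(merged) and merged[i][0] < hi:
                s, e = merged[i]
                total += min(e, hi) - s
                i += 1
            return total

        start = 0
        while start < length:
            end = min(start + window, length)
            frac = covered(start, end) / (end - start)
            rows.append((contig, start, end, frac))
            if end == length:
                break
            start += step
    return DensityTrack(rows, window, step)


# ---------------------------------------------------------------------------
# Contig joining
# ---------------------------------------------------------------------------

GAP_N = 100  # fixed gap size when no end overlap is found


@dataclass
class MergeReport:
    gapped: bool
    overlap_length: int
    identity: float
    reason: str


def merge_contigs_by_end_overlap(
    contig_a: str,
    contig_b: str,
    min_overlap: int = 1_000,
    min_identity: float = 99.0,
    max_scan: int = 50_000,
    end_slop: int = 10,
) -> tuple[str, MergeReport]:
    """Join two contigs, collapsing a suffix(A)/prefix(B) overlap once.

    If no overlap passes (``min_overlap``, ``min_identity``), the contigs are
    joined with a gap of exactly 100 N. N bases never count as matches in the
    identity computation, so N runs cannot justify a merge. A full-span
    self-identical overlap (A joined with an identical copy of itself) is
    rejected as degenerate and gapped instead.
    """
    from .search import local_search  # deferred to avoid an import cycle

    if not contig_a or not contig_b:
        raise ValueError("contigs must be non-empty")

    a_tail_off = max(0, len(contig_a) - max_scan)
    a_tail = contig_a[a_tail_off:]
    b_head = contig_b[:max_scan]

    hits = []
    if min(len(a_tail), len(b_head)) >= min_overlap:
        subject = Genome("A_tail", {"tail": a_tail})
        hits = local_search(
            b_head, subject,
            min_identity=min_identity, min_length=min_overlap)

    for hit in hits:
        if hit.strand != "+":
            continue
        # overlap must reach A's end and B's start
        if len(a_tail) - hit.s_end > end_slop or hit.q_start > end_slop:
            continue
        overlap = hit.s_end - hit.s_start
        full_span = (overlap >= len(contig_a) - end_slop
                     or hit.q_end - hit.q_start >= len(contig_b) - end_slop)
        if full_span:
            return (
                contig_a + "N" * GAP_N + contig_b,
                MergeReport(True, overlap, hit.pct_identity,
                            "rejected self-identical full-span overlap"),
            )
        drop_b = hit.q_end + (len(a_tail) - hit.s_end)
        merged = contig_a + contig_b[drop_b:]
        return merged, MergeReport(False, overlap, hit.pct_identity, "end overlap merged")

    merged = contig_a + "N" * GAP_N + contig_b
    return merged, MergeReport(True, 0, 0.0, "no end overlap passing thresholds")
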