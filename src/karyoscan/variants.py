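"""Structural-variant call filtering and classification.

Covers the size filter (>= 50 bp), the fixed/mosaic split by reference-read
support (< 3 reference reads = fixed), the multi-caller consensus filter
(>= 3 modules), the cross-sample uniqueness filter, and the classification
of deletions into TE excision, solo-LTR formation, inter-copy NAHR, or other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome import AnnotationRecord, Genome

MIN_SV_LEN = 50
FIXED_MAX_REF = 3
MIN_CALLERS = 3
BREAKPOINT_SLOP = 100   # INS treated as a point +- this many bp for overlap
EXCISION_TOL = 10       # bp tolerance on deletion-vs-annotation boundaries

VALID_TYPES = ("INS", "DEL", "INV", "TRA")


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    contig: str
    pos: int                     # 0-based
    type: str
    length: int
    ref_support: int
    alt_support: int
    caller_ids: frozenset[str]
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.type not in VALID_TYPES:
            raise ValueError(f"unknown variant type {self.type!r}")
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.ref_support < 0 or self.alt_support < 0:
            raise ValueError("support counts must be >= 0")
        if not self.caller_ids:
            raise ValueError("caller_ids must be non-empty")
        object.__setattr__(self, "caller_ids", frozenset(self.caller_ids))

    def interval(self, slop: int = BREAKPOINT_SLOP) -> tuple[int, int]:
        """Genomic footprint used for overlap tests (half-open)."""
        if self.type == "INS":
            return max(0, self.pos - slop), self.pos + slop + 1
        return self.pos, self.pos + max(1, self.length)


@dataclass
class VariantState:
    state: str                  # "fixed" | "mosaic"
    mosaic_fraction: float


def size_filter(calls: Sequence[VariantCall], min_len: int = MIN_SV_LEN
                ) -> list[VariantCall]:
    """Keep calls of at least ``min_len`` bp; translocations always pass
    (their lengths are undefined)."""
    return [c for c in calls if c.type == "TRA" or c.length >= min_len]


def classify_fixed_mosaic(call: VariantCall, fixed_max_ref: int = FIXED_MAX_REF
                          ) -> VariantState:
    """Fixed iff fewer than ``fixed_max_ref`` reads carry the reference
    allele; otherwise mosaic. The mosaic fraction alt/(alt+ref) is always
    reported."""
    total = call.ref_support + call.alt_support
    if total == 0:
        raise ValueError(f"variant at {call.contig}:{call.pos} has zero support")
    state = "fixed" if call.ref_support < fixed_max_ref else "mosaic"
    return VariantState(state, call.alt_support / total)


def consensus_filter(calls: Sequence[VariantCall], min_callers: int = MIN_CALLERS
                     ) -> list[VariantCall]:
    """Keep calls reported by at least ``min_callers`` distinct caller
    modules (caller labels are set-valued, duplicates collapse)."""
    return [c for c in calls if len(c.caller_ids) >= min_callers]


def uniqueness_filter(calls: Sequence[VariantCall],
                      slop: int = BREAKPOINT_SLOP) -> list[VariantCall]:
    """Keep calls whose genomic interval overlaps no call from any other
    sample. Insertions count as breakpoints +- ``slop`` bp since breakpoint
    coordinates jitter between callers."""
    trees: dict[str, IntervalTree] = {}
    for i, c in enumerate(calls):
        lo, hi = c.interval(slop)
        trees.setdefault(c.contig, IntervalTree()).addi(lo, hi, (i, c.sample_id))
    kept = []
    for i, c in enumerate(calls):
        lo, hi = c.interval(slop)
        clash = any(iv.data[1] != c.sample_id
                    for iv in trees[c.contig].overlap(lo, hi))
        if not clash:
            kept.append(c)
    return kept


def apply_filters(calls: Sequence[VariantCall],
                  min_len: int = MIN_SV_LEN,
                  min_callers: int = MIN_CALLERS,
                  slop: int = BREAKPOINT_SLOP) -> list[VariantCall]:
    """Size, consensus and uniqueness filters combined.

    Each filter is evaluated against the complete input call set — in
    particular, the cross-sample uniqueness test sees every raw call, not
    just those surviving the other filters — so the result does not depend
    on any filter ordering.
    """
    keep = (set(size_filter(calls, min_len))
            & set(consensus_filter(calls, min_callers))
            & set(uniqueness_filter(calls, slop)))
    return [c for c in calls if c in keep]


# ---------------------------------------------------------------------------
# Deletion-mechanism classification
# ---------------------------------------------------------------------------

@dataclass
class TEFamilyInfo:
    """Minimal family metadata needed for mechanism classification."""
    family_id: str
    te_class: str               # "DNA_TIR" | "LINE" | "LTR"
    ltr_len: int = 0


@dataclass
class DeletionMechanism:
    mechanism: str              # te_excision | solo_ltr | inter_copy_nahr | other
    copy_ids: list[str] = field(default_factory=list)
    orientation: str | None = None


def classify_deletion_mechanism(
    deletion: VariantCall,
    annotations: Sequence[AnnotationRecord],
    families: Mapping[str, TEFamilyInfo],
    boundary_tol: int = EXCISION_TOL,
    nahr_rel_tol: float = 0.25,
) -> DeletionMechanism:
    """Classify a deletion by its relation to annotated TE copies.

    - ``te_excision``: the deleted interval matches one annotated copy's
      boundaries within ``boundary_tol`` bp (excision footprints are
      imprecise, hence the tolerance).
    - ``solo_ltr``: the deletion removes the internal sequence plus one LTR
      of an LTR element, leaving a single LTR behind.
    - ``inter_copy_nahr``: the breakpoints fall in two distinct copies of the
      same family and the deletion spans roughly one copy plus the
      intervening sequence; the relative orientation of the pair is recorded.
    - ``other`` otherwise.
    """
    if deletion.type != "DEL":
        raise ValueError("mechanism classification applies to deletions")
    d_start, d_end = deletion.pos, deletion.pos + deletion.length
    here = [a for a in annotations if a.contig == deletion.contig]

    for a in here:
        if abs(d_start - a.start) <= boundary_tol and \
                abs(d_end - a.end) <= boundary_tol:
            return DeletionMechanism("te_excision", [a.copy_id])

    for a in here:
        fam = families.get(a.family_id)
        if fam is None or fam.te_class != "LTR" or fam.ltr_len <= 0:
            continue
        # removing internal + one LTR leaves the other LTR in place
        left_variant = (abs(d_start - a.start) <= boundary_tol and
                        abs(d_end - (a.end - fam.ltr_len)) <= boundary_tol)
        right_variant = (abs(d_start - (a.start + fam.ltr_len)) <= boundary_tol
                         and abs(d_end - a.end) <= boundary_tol)
        if left_variant or right_variant:
            return DeletionMechanism("solo_ltr", [a.copy_id])

    for a in here:
        for b in here:
            if a.copy_id == b.copy_id or a.family_id != b.family_id:
                continue
            if a.start >= b.start:
                continue
            start_in_a = a.start - boundary_tol <= d_start <= a.end + boundary_tol
            end_in_b = b.start - boundary_tol <= d_end <= b.end + boundary_tol
            if not (start_in_a and end_in_b):
                continue
            expected = b.start - a.start   # one copy + intervening sequence
            if abs(deletion.length - expected) <= max(
                    boundary_tol, nahr_rel_tol * expected):
                orientation = ("head_to_head" if a.strand != b.strand
                               else "head_to_tail")
                return DeletionMechanism("inter_copy_nahr",
                                         [a.copy_id, b.copy_id], orientation)

    return DeletionMechanism("other")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["sample_id", "contig", "pos", "type", "length",
                "ref_support", "alt_support", "callers"]


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [{
        "sample_id": c.sample_id, "contig": c.contig, "pos": c.pos,
        "type": c.type, "length": c.length,
        "ref_support": c.ref_support, "alt_support": c.alt_support,
        "callers": ",".join(sorted(c.caller_ids)),
    } for c in calls]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    return [
        VariantCall(
            sample_id=str(r.sample_id), contig=str(r.contig), pos=int(r.pos),
            type=str(r.type), length=int(r.length),
            ref_support=int(r.ref_support), alt_support=int(r.alt_support),
            caller_ids=frozenset(str(r.callers).split(",")),
        )
        for r in df.itertuples()
    ]


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t"))


def write_calls_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_minimal_vcf(calls: Sequence[VariantCall], path: str | Path,
                      genome: Genome | None = None) -> None:
    """Minimal VCF with symbolic ALTs and support in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description='
                 '"Variant length">\n')
        fh.write('##INFO=<ID=SUPPORT_REF,Number=1,Type=Integer,Description='
                 '"Reads supporting the reference allele">\n')
        fh.write('##INFO=<ID=SUPPORT_ALT,Number=1,Type=Integer,Description='
                 '"Reads supporting the variant allele">\n')
        fh.write('##INFO=<ID=CALLERS,Number=.,Type=String,Description='
                 '"Contributing caller modules">\n')
        fh.write('##INFO=<ID=STATE,Number=1,Type=String,Description='
                 '"fixed or mosaic">\n')
        if genome is not None:
            for name, seq in genome.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            ref = "N"
            if genome is not None and c.contig in genome.contigs:
                ref = genome.contigs[c.contig][c.pos]
            state = classify_fixed_mosaic(c).state \
                if (c.ref_support + c.alt_support) else "."
            info = (f"SVLEN={c.length};SUPPORT_REF={c.ref_support};"
                    f"SUPPORT_ALT={c.alt_support};"
                    f"CALLERS={','.join(sorted(c.caller_ids))};STATE={state}")
            fh.write(f"{c.contig}\t{c.pos + 1}\t.\t{ref}\t<{c.type}>\t.\tPASS\t"
                     f"{info}\n")
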