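"""Synthetic genomes with planted transposon events, plus generators for the
read-support, depth and methylation summaries the other modules consume.

The generator emulates the study system: an ancestral haploid assembly
carrying a TE library (DNA transposons with shared terminal inverted
repeats, 5'-truncated LINE-like elements, LTR elements with paired LTRs),
and derived protoclone-like samples carrying planted insertions (with
target-site duplications), clean excisions (leaving the TSD footprint),
solo-LTR and inter-copy NAHR deletions, and inversions — all recorded in a
truth table so recovery can be scored exactly. Every artifact is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotationRecord, Genome, revcomp, write_annotations_bed, write_fasta
from .recombination import GenotypeMatrix
from .te_load import DepthProfile
from .variants import VariantCall

_BASES = np.array(list("ACGT"))

# planted loci keep this much clearance so 5-kb flanks stay clean
EVENT_SEPARATION = 6_000
EDGE_MARGIN = 6_000


class SimulationError(ValueError):
    """Raised when a simulation plan cannot be realised."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TEFamilySpec:
    family_id: str
    te_class: str                  # "DNA_TIR" | "LINE" | "LTR"
    length: int
    tir_len: int = 28
    tir_group: str | None = None   # families sharing a TIR (superfamily)
    ltr_len: int = 300
    tsd_len: int = 8
    autonomous: bool = True

    def __post_init__(self) -> None:
        if self.te_class not in ("DNA_TIR", "LINE", "LTR"):
            raise SimulationError(f"unknown TE class {self.te_class!r}")
        if self.length <= 0:
            raise SimulationError("family length must be positive")
        if self.te_class == "LTR" and self.length <= 2 * self.ltr_len:
            raise SimulationError("LTR element shorter than its two LTRs")


@dataclass
class GenomeSpec:
    contig_lengths: tuple[int, ...] = (200_000,)
    gc: float = 0.47


@dataclass
class EventPlan:
    sample_id: str
    n_insertions: int = 0
    n_excisions: int = 0
    n_solo_ltr: int = 0
    n_nahr: int = 0
    n_inversions: int = 0


@dataclass
class SupportModel:
    total_reads: int = 40
    n_callers: int = 5
    p_fixed: float = 12 / 72       # fraction of events fixed in the mycelium


@dataclass
class DepthModel:
    base_cov: float = 35.0
    dispersion: float = 8.0        # negative-binomial shape; -> inf is Poisson
    cross_map_rate: float = 0.02   # residual depth on absent families


@dataclass
class MethylationModel:
    repeat_mean: float = 0.76
    nonrepeat_mean: float = 0.20
    concentration: float = 8.0     # Beta concentration around the class mean
    reads_per_site: float = 20.0
    frac_fail_mapq: float = 0.05
    frac_secondary: float = 0.05
    frac_short_span: float = 0.05
    max_sites_per_class: int = 3_000


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    te_library: list[TEFamilySpec] = field(default_factory=list)
    ancestral_copies: dict[str, int] = field(default_factory=dict)
    paired_families: list[str] = field(default_factory=list)
    copy_divergence: float = 0.003     # per-base substitution rate per copy
    pair_gap: int = 2_500              # spacing inside a planted NAHR pair
    plans: list[EventPlan] = field(default_factory=list)
    support: SupportModel = field(default_factory=SupportModel)
    depth: DepthModel = field(default_factory=DepthModel)
    methylation: MethylationModel = field(default_factory=MethylationModel)


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults: a 200-kb ancestral genome, a five-family TE
    library (hAT-like autonomous + nonautonomous sharing TIRs, a Mariner-like
    element, a 5'-truncating LINE, a Gypsy-like LTR element with a planted
    direct pair), and two protoclone-like samples with 5 insertions + 5
    excisions each plus a third sample carrying the deletion/inversion
    mechanisms."""
    library = [
        TEFamilySpec("hAT_auto", "DNA_TIR", 3396, tir_len=28, tir_group="hAT",
                     tsd_len=8, autonomous=True),
        TEFamilySpec("hAT_na", "DNA_TIR", 2765, tir_len=28, tir_group="hAT",
                     tsd_len=8, autonomous=False),
        TEFamilySpec("TcMar_na", "DNA_TIR", 1120, tir_len=30, tsd_len=2,
                     autonomous=False),
        TEFamilySpec("LINE_tad", "LINE", 4000, tsd_len=10),
        TEFamilySpec("Gypsy_ltr", "LTR", 4800, ltr_len=300, tsd_len=5),
    ]
    return SimulationConfig(
        seed=seed,
        te_library=library,
        ancestral_copies={"hAT_auto": 2, "hAT_na": 5, "TcMar_na": 5,
                          "LINE_tad": 3, "Gypsy_ltr": 3},
        paired_families=["Gypsy_ltr"],
        plans=[
            EventPlan("protoclone_1", n_insertions=5, n_excisions=5),
            EventPlan("protoclone_2", n_insertions=5, n_excisions=5),
            EventPlan("protoclone_3", n_solo_ltr=1, n_nahr=1, n_inversions=1),
        ],
    )


# ---------------------------------------------------------------------------
# Ancestral genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protect: tuple[int, int] | None = None) -> str:
    """Substitute bases at the given per-base rate; ``protect`` shields a
    half-open interval (e.g. identical LTRs) from change."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        if protect and protect[0] <= i < protect[1]:
            continue
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def build_family_consensus(config: SimulationConfig, rng: np.random.Generator
                           ) -> dict[str, str]:
    """Family consensus sequences; DNA families in the same tir_group share
    their terminal inverted repeat, LTR families carry two identical LTRs."""
    group_tirs: dict[str, str] = {}
    consensus: dict[str, str] = {}
    for fam in config.te_library:
        if fam.te_class == "DNA_TIR":
            key = fam.tir_group or fam.family_id
            if key not in group_tirs or len(group_tirs[key]) != fam.tir_len:
                group_tirs[key] = _random_seq(rng, fam.tir_len, config.genome.gc)
            tir = group_tirs[key][:fam.tir_len]
            core = _random_seq(rng, fam.length - 2 * fam.tir_len,
                               config.genome.gc)
            # the TIR must end where specified: the first core base may not
            # pair with the last, or the inverted repeat would run on
            if core[0] == revcomp(core[-1]):
                core = ("A" if core[0] != "A" else "C") + core[1:]
                if core[0] == revcomp(core[-1]):
                    core = ("G" if core[0] != "G" else "T") + core[1:]
            consensus[fam.family_id] = tir + core + revcomp(tir)
        elif fam.te_class == "LTR":
            ltr = _random_seq(rng, fam.ltr_len, config.genome.gc)
            internal = _random_seq(rng, fam.length - 2 * fam.ltr_len,
                                   config.genome.gc)
            consensus[fam.family_id] = ltr + internal + ltr
        else:
            consensus[fam.family_id] = _random_seq(rng, fam.length,
                                                   config.genome.gc)
    return consensus


@dataclass
class AncestralSimulation:
    genome: Genome
    annotations: list[AnnotationRecord]
    consensus: dict[str, str]
    families: dict[str, TEFamilySpec]
    config: SimulationConfig


def simulate_ancestral(config: SimulationConfig) -> AncestralSimulation:
    """Plant TE copies into random background sequence.

    Copies are placed in shuffled order with uniformly distributed gaps, a
    minimum inter-copy separation and an edge margin so that every planted
    locus has clean 5-kb flanks; each copy is planted between two copies of
    its target-site duplication; LINE copies are 5'-truncated; the first two
    copies of each family in ``paired_families`` are planted as a close
    direct pair (NAHR substrate).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    families = {f.family_id: f for f in config.te_library}
    consensus = build_family_consensus(config, rng)

    # realised copy sequences
    copy_seqs: list[tuple[str, str]] = []      # (family_id, sequence)
    for fam_id, count in config.ancestral_copies.items():
        fam = families[fam_id]
        for _ in range(count):
            seq = consensus[fam_id]
            if fam.te_class == "LINE":
                trunc = int(len(seq) * rng.uniform(0.1, 0.6))
                seq = seq[trunc:]
            if fam.te_class == "LTR":
                seq = _mutate(rng, seq, config.copy_divergence,
                              protect=(0, fam.ltr_len))
                # keep the two LTRs identical
                seq = seq[:len(seq) - fam.ltr_len] + seq[:fam.ltr_len]
            else:
                seq = _mutate(rng, seq, config.copy_divergence)
            copy_seqs.append((fam_id, seq))

    # blocks: paired families contribute one two-copy block
    blocks: list[list[tuple[str, str]]] = []
    used = set()
    for fam_id in config.paired_families:
        idxs = [i for i, (f, _) in enumerate(copy_seqs) if f == fam_id][:2]
        if len(idxs) == 2:
            blocks.append([copy_seqs[i] for i in idxs])
            used.update(idxs)
    for i, cs in enumerate(copy_seqs):
        if i not in used:
            blocks.append([cs])
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # distribute blocks across contigs proportionally to length
    n_contigs = len(config.genome.contig_lengths)
    assignment: list[list[list[tuple[str, str]]]] = [[] for _ in range(n_contigs)]
    for i, b in enumerate(blocks):
        assignment[i % n_contigs].append(b)

    def block_len(b: list[tuple[str, str]]) -> int:
        total = sum(len(s) + 2 * families[f].tsd_len for f, s in b)
        if len(b) > 1:
            total += config.pair_gap * (len(b) - 1)
        return total

    contigs: dict[str, str] = {}
    annotations: list[AnnotationRecord] = []
    counter = 0
    for ci, contig_blocks in enumerate(assignment):
        L = config.genome.contig_lengths[ci]
        name = f"contig_{ci + 1}"
        n = len(contig_blocks)
        need = (sum(block_len(b) for b in contig_blocks)
                + 2 * EDGE_MARGIN + max(0, n - 1) * EVENT_SEPARATION)
        slack = L - need
        if slack < 0:
            raise SimulationError(
                f"{name}: {n} blocks need {need} bp but contig is {L} bp")
        extras = np.diff(np.concatenate(
            [[0.0], np.sort(rng.uniform(0, slack, size=n)), [float(slack)]])) \
            if n else np.array([float(slack)])
        pieces: list[str] = []
        cursor = 0

        def emit_bg(length: int) -> None:
            nonlocal cursor
            pieces.append(_random_seq(rng, length, config.genome.gc))
            cursor += length

        emit_bg(EDGE_MARGIN + int(extras[0]))
        for bi, b in enumerate(contig_blocks):
            for fi, (fam_id, seq) in enumerate(b):
                fam = families[fam_id]
                k = fam.tsd_len
                d = _random_seq(rng, k, config.genome.gc)
                strand = "+" if rng.random() < 0.5 else "-"
                planted = seq if strand == "+" else revcomp(seq)
                pieces.append(d)
                start = cursor + k
                pieces.append(planted)
                pieces.append(d)
                counter += 1
                annotations.append(AnnotationRecord(
                    name, start, start + len(planted), strand, fam_id,
                    f"{fam_id}.c{counter}"))
                cursor = start + len(planted) + k
                if fi < len(b) - 1:
                    emit_bg(config.pair_gap)
            if bi < n - 1:
                emit_bg(EVENT_SEPARATION + int(extras[bi + 1]))
        emit_bg(L - cursor)
        contigs[name] = "".join(pieces)
        assert len(contigs[name]) == L

    genome = Genome("ancestral", contigs)
    annotations.sort(key=lambda r: (r.contig, r.start))
    return AncestralSimulation(genome, annotations, consensus, families, config)


# ---------------------------------------------------------------------------
# Derived samples
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["sample_id", "event_type", "family_id", "copy_id",
                 "source_copy_id", "contig", "anc_start", "anc_end",
                 "derived_start", "derived_end", "length", "tsd",
                 "mosaic_fraction"]


@dataclass
class DerivedSample:
    genome: Genome
    annotations: list[AnnotationRecord]
    truth: pd.DataFrame


def _draw_fraction(rng: np.random.Generator, p_fixed: float) -> float:
    if rng.random() < p_fixed:
        return 1.0
    return float(rng.uniform(0.1, 0.9))


def derive_sample(anc: AncestralSimulation, plan: EventPlan, seed: int
                  ) -> DerivedSample:
    """Apply a planted-event plan to the ancestral genome.

    Events never overlap, keep :data:`EVENT_SEPARATION` bp of clearance from
    each other and from contig ends, and are recorded in the truth table in
    both ancestral and derived coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([anc.config.seed, 2, seed]))
    fams = anc.families
    p_fixed = anc.config.support.p_fixed

    paired_ids: set[str] = set()
    by_fam: dict[str, list[AnnotationRecord]] = {}
    for a in anc.annotations:
        by_fam.setdefault(a.family_id, []).append(a)
    for fam_id in anc.config.paired_families:
        copies = sorted(by_fam.get(fam_id, []), key=lambda a: (a.contig, a.start))
        for x, y in zip(copies, copies[1:]):
            if x.contig == y.contig and y.start - x.end <= 4 * anc.config.pair_gap:
                paired_ids.update((x.copy_id, y.copy_id))
                break

    taken: set[str] = set()

    def pick(predicate, what: str, n: int) -> list[AnnotationRecord]:
        pool = [a for a in anc.annotations
                if a.copy_id not in taken and a.copy_id not in paired_ids
                and predicate(a)]
        if len(pool) < n:
            raise SimulationError(
                f"{plan.sample_id}: cannot place {n} {what} events "
                f"({len(pool)} eligible copies)")
        chosen = [pool[i] for i in sorted(
            rng.choice(len(pool), size=n, replace=False))]
        taken.update(c.copy_id for c in chosen)
        return chosen

    # edits: (contig, anc_start, anc_end, replacement, truth-row stub)
    edits: list[tuple[str, int, int, str, dict]] = []

    for a in pick(lambda a: fams[a.family_id].te_class == "DNA_TIR",
                  "excision", plan.n_excisions):
        edits.append((a.contig, a.start, a.end, "", {
            "event_type": "excision", "family_id": a.family_id,
            "copy_id": a.copy_id, "source_copy_id": ".",
            "length": a.length, "tsd": ".",
        }))

    for a in pick(lambda a: fams[a.family_id].te_class == "LTR",
                  "solo_ltr", plan.n_solo_ltr):
        ltr = fams[a.family_id].ltr_len
        edits.append((a.contig, a.start, a.end - ltr, "", {
            "event_type": "solo_ltr", "family_id": a.family_id,
            "copy_id": a.copy_id, "source_copy_id": ".",
            "length": a.length - ltr, "tsd": ".",
        }))

    if plan.n_nahr:
        if plan.n_nahr > 1 or len(paired_ids) < 2:
            raise SimulationError(
                f"{plan.sample_id}: NAHR needs one planted copy pair")
        pair = sorted((a for a in anc.annotations if a.copy_id in paired_ids),
                      key=lambda a: a.start)
        a, b = pair
        edits.append((a.contig, a.start, b.start, "", {
            "event_type": "nahr_deletion", "family_id": a.family_id,
            "copy_id": f"{a.copy_id},{b.copy_id}", "source_copy_id": ".",
            "length": b.start - a.start, "tsd": ".",
        }))

    for a in pick(lambda a: True, "inversion", plan.n_inversions):
        seg = anc.genome.slice(a.contig, a.start, a.end)
        edits.append((a.contig, a.start, a.end, revcomp(seg), {
            "event_type": "inversion", "family_id": a.family_id,
            "copy_id": a.copy_id, "source_copy_id": ".",
            "length": a.length, "tsd": ".",
        }))

    # insertion targets: sampled from background kept clear of every other
    # event locus and of existing annotations
    if plan.n_insertions:
        free: dict[str, list[tuple[int, int]]] = {
            name: [(EDGE_MARGIN, anc.genome.contig_length(name) - EDGE_MARGIN)]
            for name in anc.genome.contigs
        }

        def block(contig: str, lo: int, hi: int) -> None:
            out = []
            for s, e in free[contig]:
                if hi <= s or lo >= e:
                    out.append((s, e))
                    continue
                if s < lo:
                    out.append((s, lo))
                if hi < e:
                    out.append((hi, e))
            free[contig] = out

        for contig, s, e, _, _ in edits:
            block(contig, s - EVENT_SEPARATION, e + EVENT_SEPARATION)
        for a in anc.annotations:
            pad = fams[a.family_id].tsd_len + 50
            block(a.contig, a.start - pad, a.end + pad)

        sources = list(anc.annotations)
        for _ in range(plan.n_insertions):
            total = sum(e - s for ivs in free.values() for s, e in ivs)
            if total <= 0:
                raise SimulationError(
                    f"{plan.sample_id}: no room left for an insertion target")
            r = int(rng.integers(total))
            target = None
            for contig, ivs in free.items():
                for s, e in ivs:
                    if r < e - s:
                        target = (contig, s + r)
                        break
                    r -= e - s
                if target:
                    break
            contig, t = target
            src = sources[int(rng.integers(len(sources)))]
            te_seq = anc.genome.slice(src.contig, src.start, src.end)
            k = fams[src.family_id].tsd_len
            d = anc.genome.slice(contig, t, t + k)
            edits.append((contig, t + k, t + k, te_seq + d, {
                "event_type": "insertion", "family_id": src.family_id,
                "copy_id": f"{src.family_id}.ins{t}", "source_copy_id": src.copy_id,
                "length": len(te_seq), "tsd": d if k else ".",
            }))
            block(contig, t - EVENT_SEPARATION, t + EVENT_SEPARATION)

    # ---- apply edits right-to-left is unnecessary: build piecewise ----
    edits.sort(key=lambda e: (e[0], e[1]))
    for (c1, s1, e1, *_), (c2, s2, e2, *_) in zip(edits, edits[1:]):
        if c1 == c2 and e1 > s2:
            raise SimulationError("internal error: overlapping edits")

    truth_rows: list[dict] = []
    new_contigs: dict[str, str] = {}
    derived_annotations: list[AnnotationRecord] = []
    for name, seq in anc.genome.contigs.items():
        contig_edits = [e for e in edits if e[0] == name]
        pieces = []
        prev = 0
        offset = 0
        spans: dict[int, tuple[int, int]] = {}   # edit index -> derived span
        for idx, (_, s, e, repl, stub) in enumerate(contig_edits):
            pieces.append(seq[prev:s])
            pieces.append(repl)
            spans[idx] = (s + offset, s + offset + len(repl))
            offset += len(repl) - (e - s)
            prev = e
        pieces.append(seq[prev:])
        new_contigs[name] = "".join(pieces)

        # truth rows with derived coordinates
        for idx, (_, s, e, repl, stub) in enumerate(contig_edits):
            ds, de = spans[idx]
            row = dict(stub)
            row.update({
                "sample_id": plan.sample_id, "contig": name,
                "anc_start": s, "anc_end": e,
                "mosaic_fraction": _draw_fraction(rng, p_fixed),
            })
            if row["event_type"] == "insertion":
                k = fams[row["family_id"]].tsd_len
                row["derived_start"] = ds
                row["derived_end"] = de - k     # the TE body, TSD excluded
                row["anc_start"] = s - k        # the target site
                row["anc_end"] = s - k
            elif row["event_type"] == "inversion":
                row["derived_start"], row["derived_end"] = ds, de
            else:                               # deletions: junction point
                row["derived_start"] = ds
                row["derived_end"] = ds
            truth_rows.append(row)

        # carry annotations over
        for a in (x for x in anc.annotations if x.contig == name):
            shift = 0
            dropped = False
            solo_from = None
            inverted = False
            for _, s, e, repl, stub in contig_edits:
                if e <= a.start:
                    shift += len(repl) - (e - s)
                elif s >= a.end:
                    continue
                else:  # edit intersects the copy
                    et = stub["event_type"]
                    if et in ("excision", "nahr_deletion"):
                        dropped = True
                    elif et == "solo_ltr" and stub["copy_id"] == a.copy_id:
                        solo_from = (s, e)
                    elif et == "inversion" and stub["copy_id"] == a.copy_id:
                        inverted = True
                    break
            if dropped:
                continue
            if solo_from is not None:
                s, e = solo_from
                ltr = fams[a.family_id].ltr_len
                derived_annotations.append(AnnotationRecord(
                    name, s + shift, s + shift + ltr, a.strand, a.family_id,
                    a.copy_id + "_solo"))
                continue
            derived_annotations.append(AnnotationRecord(
                name, a.start + shift, a.end + shift,
                ("-" if a.strand == "+" else "+") if inverted else a.strand,
                a.family_id, a.copy_id + ("_inv" if inverted else "")))

    # new insertion annotations
    for row in truth_rows:
        if row["event_type"] == "insertion":
            src_strand = next(a.strand for a in anc.annotations
                              if a.copy_id == row["source_copy_id"])
            derived_annotations.append(AnnotationRecord(
                row["contig"], row["derived_start"], row["derived_end"],
                src_strand, row["family_id"], row["copy_id"]))

    derived_annotations.sort(key=lambda r: (r.contig, r.start))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return DerivedSample(Genome(plan.sample_id, new_contigs),
                         derived_annotations, truth)


# ---------------------------------------------------------------------------
# Read support
# ---------------------------------------------------------------------------

_EVENT_TO_SVTYPE = {"insertion": "INS", "excision": "DEL", "solo_ltr": "DEL",
                    "nahr_deletion": "DEL", "inversion": "INV"}


def simulate_read_support(truth: pd.DataFrame, total_reads: int, seed: int,
                          n_callers: int = 5) -> list[VariantCall]:
    """Binomially sampled read support for each planted event.

    alt_support ~ Binomial(total_reads, mosaic_fraction); each of the
    ``n_callers`` caller modules reports the event with a probability that
    grows with its mosaic fraction (high-fraction variants are easy for
    every caller), with at least one caller always reporting.
    """
    if total_reads < 1:
        raise SimulationError("total_reads must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    calls = []
    for row in truth.itertuples():
        f = float(row.mosaic_fraction)
        alt = int(rng.binomial(total_reads, f))
        p_detect = min(1.0, 0.3 + 0.7 * f)
        detected = [f"caller_{i + 1}" for i in range(n_callers)
                    if rng.random() < p_detect]
        if not detected:
            detected = [f"caller_{1 + int(rng.integers(n_callers))}"]
        pos = int(row.derived_start)
        calls.append(VariantCall(
            sample_id=row.sample_id, contig=row.contig, pos=pos,
            type=_EVENT_TO_SVTYPE[row.event_type], length=int(row.length),
            ref_support=total_reads - alt, alt_support=alt,
            caller_ids=frozenset(detected)))
    return calls


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

def simulate_depth_profiles(
    copy_numbers: Mapping[str, Mapping[str, float]],
    consensus_lengths: Mapping[str, int],
    seed: int,
    base_cov: float = 35.0,
    dispersion: float = 8.0,
    cross_map_rate: float = 0.02,
    raw_cov_range: tuple[float, float] = (1.2, 2.5),
) -> list[DepthProfile]:
    """Per-position depth over each family consensus for each sample.

    Each sample sequences at its own raw single-copy coverage (a uniform
    multiple of ``base_cov``, emulating uneven sequencing effort) which the
    downstream 35x normalization scales away. Depth ~ NegativeBinomial with
    mean copy_number x raw coverage (+ a small cross-mapping floor so absent
    families are near zero but not silent); dispersion -> infinity
    approaches Poisson.
    """
    if base_cov <= 0:
        raise SimulationError("base_cov must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))

    def nb(mean: float, size: int) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size)
        r = dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size).astype(float)

    profiles = []
    for sample, fams in copy_numbers.items():
        raw_cov = base_cov * rng.uniform(*raw_cov_range)
        depths = {}
        for fam, cn in fams.items():
            mean = cn * raw_cov + cross_map_rate * raw_cov
            depths[fam] = nb(mean, consensus_lengths[fam])
        single_copy = nb(raw_cov, 5_000)
        profiles.append(DepthProfile(
            sample_id=sample, family_depths=depths,
            observed_single_copy_median=float(np.median(single_copy))))
    return profiles


def simulate_population_copy_numbers(
    family_base: Mapping[str, float],
    family_spread: Mapping[str, float],
    n_samples: int,
    seed: int,
) -> dict[str, dict[str, float]]:
    """Integer copy numbers per (sample, family): Normal(base, spread)
    rounded and clipped at zero — families with larger spread model higher
    population load variance."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    out: dict[str, dict[str, float]] = {}
    for i in range(n_samples):
        sample = f"ring_{i + 1}"
        out[sample] = {
            fam: float(max(0, round(rng.normal(base, family_spread[fam]))))
            for fam, base in family_base.items()
        }
    return out


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    genome: Genome,
    repeat_intervals: Sequence[tuple[str, int, int]],
    model: MethylationModel,
    seed: int,
) -> pd.DataFrame:
    """Per-read CpG methylation calls over the genome's actual CpG sites.

    Each site draws a latent frequency from a Beta centred on its class mean
    (repeat vs non-repeat), then per-read Bernoulli calls; read attributes
    (mapq, primary flag, aligned span) are drawn so the configured fraction
    fails each mapping filter.
    """
    if not (0 <= model.repeat_mean <= 1 and 0 <= model.nonrepeat_mean <= 1):
        raise SimulationError("methylation means must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    from intervaltree import IntervalTree
    trees: dict[str, IntervalTree] = {}
    for contig, s, e in repeat_intervals:
        trees.setdefault(contig, IntervalTree()).addi(s, e)

    sites: dict[bool, list[tuple[str, int]]] = {True: [], False: []}
    for contig, seq in genome.contigs.items():
        tree = trees.get(contig)
        start = 0
        while True:
            i = seq.find("CG", start)
            if i < 0:
                break
            in_rep = bool(tree and tree.overlaps_point(i))
            sites[in_rep].append((contig, i))
            start = i + 1
    for flag in (True, False):
        if len(sites[flag]) > model.max_sites_per_class:
            idx = rng.choice(len(sites[flag]), size=model.max_sites_per_class,
                             replace=False)
            sites[flag] = [sites[flag][i] for i in sorted(idx)]

    rows = []
    read_no = 0
    for in_rep, mean in ((True, model.repeat_mean),
                         (False, model.nonrepeat_mean)):
        a = mean * model.concentration
        b = (1 - mean) * model.concentration
        for contig, pos in sites[in_rep]:
            latent = rng.beta(a, b)
            n_reads = max(1, int(rng.poisson(model.reads_per_site)))
            for _ in range(n_reads):
                read_no += 1
                mapq = 30 if rng.random() < model.frac_fail_mapq else 60
                primary = 0 if rng.random() < model.frac_secondary else 1
                span = (int(rng.integers(1_000, 6_000))
                        if rng.random() < model.frac_short_span
                        else int(rng.integers(6_000, 20_000)))
                rows.append((f"read_{read_no}", contig, pos,
                             int(rng.random() < latent), mapq, primary, span))
    df = pd.DataFrame(rows, columns=["read_id", "contig", "pos", "methylated",
                                     "mapq", "primary", "span"])
    return df.sort_values(["contig", "pos", "read_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

def simulate_genotype_matrix(
    seed: int,
    n_sites: int = 1_000,
    n_per_group: int = 4,
    callable_length: int = 100_000,
    noise: float = 0.0,
    missing_rate: float = 0.01,
    swapped_block: tuple[str, int, int] | None = None,
) -> GenotypeMatrix:
    """Haploid genotype matrix for two clonal nucleotype groups.

    Group A carries allele 0 and group B allele 1 at every variant site
    (protoclones of the same nucleotype are clonal, so within-group noise
    defaults to zero); calls are dropped to missing at ``missing_rate``. The
    site count's default is calibrated so that, with 4+4 samples and the
    default callable length, expected nucleotide diversity matches the
    ~0.56% divergence between the two nucleotypes. ``swapped_block``
    = (sample, first_site_index, n_sites) plants a mitotic-recombination
    tract: that sample takes the other group's allele at those consecutive
    sites.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    if n_sites > callable_length:
        raise SimulationError("more sites than callable positions")
    pos = np.sort(rng.choice(callable_length, size=n_sites, replace=False))
    samples = [f"A{i + 1}" for i in range(n_per_group)] + \
              [f"B{i + 1}" for i in range(n_per_group)]
    groups = {s: s[0] for s in samples}
    geno = np.zeros((n_sites, 2 * n_per_group), dtype=np.int8)
    geno[:, n_per_group:] = 1
    if noise > 0:
        flips = rng.random(geno.shape) < noise
        geno = np.where(flips, 1 - geno, geno)
    if missing_rate > 0:
        geno = np.where(rng.random(geno.shape) < missing_rate, -1, geno)
    if swapped_block is not None:
        sample, first, k = swapped_block
        j = samples.index(sample)
        other = 1 if groups[sample] == "A" else 0
        geno[first:first + k, j] = other
    sites = pd.DataFrame({"contig": "contig_1", "pos": pos})
    return GenotypeMatrix(sites, samples, geno, groups)


# ---------------------------------------------------------------------------
# Bundled default simulation and emitters
# ---------------------------------------------------------------------------

@dataclass
class SimulationBundle:
    ancestral: AncestralSimulation
    samples: dict[str, DerivedSample]
    truth: pd.DataFrame
    support_calls: list[VariantCall]


def run_default_simulation(seed: int = 0,
                           config: SimulationConfig | None = None
                           ) -> SimulationBundle:
    """Ancestral genome + all planned derived samples + read support."""
    cfg = config or default_config(seed)
    anc = simulate_ancestral(cfg)
    samples: dict[str, DerivedSample] = {}
    truths = []
    for i, plan in enumerate(cfg.plans):
        d = derive_sample(anc, plan, seed=i)
        samples[plan.sample_id] = d
        truths.append(d.truth)
    truth = pd.concat(truths, ignore_index=True) if truths \
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    support = simulate_read_support(truth, cfg.support.total_reads,
                                    seed=cfg.seed,
                                    n_callers=cfg.support.n_callers)
    return SimulationBundle(anc, samples, truth, support)


def write_simulation(bundle: SimulationBundle, outdir: str | Path) -> None:
    """Emit FASTAs, BED annotations, the truth table and support TSV."""
    from .variants import write_calls_tsv
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.ancestral.genome, outdir / "ancestral.fasta")
    write_annotations_bed(bundle.ancestral.annotations,
                          outdir / "ancestral.bed")
    cons = Genome("consensus", dict(bundle.ancestral.consensus))
    write_fasta(cons, outdir / "te_consensus.fasta")
    for sample_id, d in bundle.samples.items():
        write_fasta(d.genome, outdir / f"{sample_id}.fasta")
        write_annotations_bed(d.annotations, outdir / f"{sample_id}.bed")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_calls_tsv(bundle.support_calls, outdir / "support.tsv")
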