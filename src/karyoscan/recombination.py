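"""Mitotic-recombination scan over a haploid genotype matrix.

Two groups of haploid samples (nucleotypes A and B) are compared site by
site. A signal of mitotic recombination or gene conversion is a run of at
least two consecutive variant sites where one focal sample has swapped to
the other group's consensus genotype. Nucleotide diversity (pi) is computed
as average pairwise differences per callable site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
MIN_RUN = 2


@dataclass
class RecombTract:
    sample_id: str
    contig: str
    first_site: int             # position (bp) of the first discordant site
    last_site: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("tract must span at least one site")


@dataclass
class GenotypeMatrix:
    """Biallelic haploid genotype calls, sites x samples.

    ``genotypes`` holds 0/1 with -1 for missing; ``sites`` is a DataFrame
    with columns (contig, pos) sorted by (contig, pos); ``groups`` maps every
    sample id to its nucleotype label.
    """

    sites: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if set(self.samples) - set(self.groups):
            raise ValueError("every sample needs a group label")
        expected = self.sites.sort_values(["contig", "pos"]).reset_index(drop=True)
        if not expected[["contig", "pos"]].equals(
                self.sites[["contig", "pos"]].reset_index(drop=True)):
            raise ValueError("sites must be sorted by (contig, pos)")
        bad = set(np.unique(self.genotypes)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"genotypes must be biallelic 0/1/missing, got {bad}")

    def group_members(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if self.groups[s] == group]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: Mapping[str, str]
                   ) -> "GenotypeMatrix":
        """Build from a site x sample table with 'contig' and 'pos' columns;
        remaining columns are samples (values 0/1, '.' or NaN missing)."""
        df = df.sort_values(["contig", "pos"]).reset_index(drop=True)
        samples = [c for c in df.columns if c not in ("contig", "pos")]
        geno = np.full((len(df), len(samples)), MISSING, dtype=np.int8)
        for j, s in enumerate(samples):
            col = df[s].mask(df[s].astype(str) == ".", MISSING)
            geno[:, j] = pd.to_numeric(col).fillna(MISSING).astype(np.int8)
        return cls(df[["contig", "pos"]].copy(), samples, geno, dict(groups))

    @classmethod
    def from_vcf(cls, path: str | Path, groups: Mapping[str, str]
                 ) -> "GenotypeMatrix":
        """Read haploid GTs from a (plain-text) VCF; multiallelic sites are
        dropped, matching the biallelic-only contract."""
        rows = []
        samples: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                f = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = f[9:]
                    continue
                if "," in f[4]:      # multiallelic
                    continue
                gts = []
                for cell in f[9:]:
                    gt = cell.split(":")[0]
                    gts.append(MISSING if gt in (".", "./.") else int(gt[0]))
                rows.append((f[0], int(f[1]) - 1, gts))
        sites = pd.DataFrame({"contig": [r[0] for r in rows],
                              "pos": [r[1] for r in rows]})
        geno = np.array([r[2] for r in rows], dtype=np.int8) \
            if rows else np.empty((0, len(samples)), dtype=np.int8)
        order = sites.sort_values(["contig", "pos"]).index
        return cls(sites.loc[order].reset_index(drop=True), samples,
                   geno[order.to_numpy()], dict(groups))


def group_consensus(matrix: GenotypeMatrix, group: str) -> np.ndarray:
    """Per-site majority allele among non-missing calls; ties and all-missing
    sites are reported missing."""
    members = matrix.group_members(group)
    if not members:
        raise ValueError(f"group {group!r} has no samples")
    sub = matrix.genotypes[:, members]
    ones = (sub == 1).sum(axis=1)
    zeros = (sub == 0).sum(axis=1)
    cons = np.full(len(matrix.sites), MISSING, dtype=np.int8)
    cons[ones > zeros] = 1
    cons[zeros > ones] = 0
    return cons


def find_discordant_runs(
    matrix: GenotypeMatrix,
    focal_sample: str,
    min_run: int = MIN_RUN,
    mask: np.ndarray | None = None,
) -> list[RecombTract]:
    """Maximal runs of consecutive sites where the focal sample has swapped
    group genotype.

    A site is discordant iff the focal genotype differs from its own group's
    consensus AND equals the other group's consensus, with all three calls
    non-missing. Missing (or masked) sites break runs: succession means
    adjacency in the filtered, sorted site list of a contig, not base-pair
    distance. ``mask`` marks low-mappability sites to exclude, standing in
    for read-level visual review.
    """
    if focal_sample not in matrix.samples:
        raise ValueError(f"unknown sample {focal_sample!r}")
    own = matrix.groups[focal_sample]
    others = sorted(set(matrix.groups.values()) - {own})
    if len(others) != 1:
        raise ValueError("exactly two groups are required")
    cons_own = group_consensus(matrix, own)
    cons_other = group_consensus(matrix, others[0])
    focal = matrix.genotypes[:, matrix.samples.index(focal_sample)]

    ok = (focal != MISSING) & (cons_own != MISSING) & (cons_other != MISSING)
    if mask is not None:
        ok &= ~np.asarray(mask, dtype=bool)
    discordant = ok & (focal != cons_own) & (focal == cons_other)

    tracts: list[RecombTract] = []
    contigs = matrix.sites["contig"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    run_start = None
    for i in range(len(discordant) + 1):
        in_run = (i < len(discordant) and discordant[i]
                  and (run_start is None or contigs[i] == contigs[run_start]))
        if in_run:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            n = i - run_start
            if n >= min_run:
                tracts.append(RecombTract(
                    focal_sample, contigs[run_start],
                    int(positions[run_start]), int(positions[i - 1]), n))
            run_start = i if (i < len(discordant) and discordant[i]) else None
    return tracts


def nucleotide_diversity(matrix: GenotypeMatrix, callable_length: int) -> float:
    """pi = average pairwise differences per callable site across all sample
    pairs; pairs are compared at sites where both calls are present."""
    if callable_length <= 0:
        raise ValueError("callable_length must be positive")
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need at least two samples")
    total = 0
    pairs = 0
    for i, j in combinations(range(n), 2):
        gi = matrix.genotypes[:, i]
        gj = matrix.genotypes[:, j]
        both = (gi != MISSING) & (gj != MISSING)
        total += int(((gi != gj) & both).sum())
        pairs += 1
    return total / (pairs * callable_length)


def nucleotide_diversity_from_sequences(seqs: Sequence[str]) -> float:
    """pi from aligned equal-length haplotype sequences (per-site)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    if length == 0 or any(len(s) != length for s in seqs):
        raise ValueError("sequences must be non-empty and equal length")
    total = 0
    pairs = 0
    for a, b in combinations(seqs, 2):
        total += sum(1 for x, y in zip(a, b) if x != y)
        pairs += 1
    return total / (pairs * length)


def tracts_to_frame(tracts: Sequence[RecombTract]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": t.sample_id, "contig": t.contig,
        "first_site": t.first_site, "last_site": t.last_site,
        "n_sites": t.n_sites,
    } for t in tracts])
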