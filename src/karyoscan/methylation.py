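"""Per-CpG methylation frequencies from per-read calls, and the
repeat-vs-non-repeat comparison.

Per-read methylation calls (as emitted by a long-read methylation caller)
are filtered to reads with mapq 60, primary alignments and an uninterrupted
aligned span of at least 6 kb — the filters that, on dikaryon data, keep
only reads confidently assigned to one nucleotype. Frequencies are then
aggregated per CpG site, sites are split by repeat-annotation overlap, and
the two classes are compared with a two-sided Wilcoxon rank-sum test on
repeated balanced downsamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

MIN_MAPQ = 60
MIN_SPAN = 6_000
N_DOWNSAMPLE = 500

READ_COLUMNS = ["read_id", "contig", "pos", "methylated", "mapq", "primary",
                "span"]


@dataclass
class MethylationComparison:
    mean_repeat: float
    mean_nonrepeat: float
    statistic: float            # median rank-sum statistic across downsamples
    p_value: float              # median two-sided p across downsamples
    n_repeat: int
    n_nonrepeat: int
    n_downsample: int
    downsample_size: int


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def filter_reads(
    records: pd.DataFrame,
    min_mapq: int = MIN_MAPQ,
    require_primary: bool = True,
    min_span: int = MIN_SPAN,
) -> pd.DataFrame:
    """Keep per-read calls from reads passing all three mapping filters:
    mapq >= ``min_mapq``, primary alignment, aligned reference span >=
    ``min_span`` (clipping excluded). Idempotent; output is a row subset."""
    keep = (records["mapq"] >= min_mapq) & (records["span"] >= min_span)
    if require_primary:
        keep &= records["primary"].astype(bool)
    return records.loc[keep].copy()


def site_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (contig, pos) with >= 1 call: methylated and total call
    counts and their ratio."""
    if records.empty:
        return pd.DataFrame(columns=["contig", "pos", "methylated_calls",
                                     "total_calls", "frequency"])
    grouped = records.groupby(["contig", "pos"], sort=True)["methylated"].agg(
        methylated_calls="sum", total_calls="count").reset_index()
    grouped["frequency"] = grouped["methylated_calls"] / grouped["total_calls"]
    return grouped


def annotate_repeats(
    sites: pd.DataFrame,
    repeat_intervals: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Add an ``in_repeat`` flag by overlap with repeat intervals
    (half-open, per contig)."""
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in repeat_intervals:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    sites = sites.copy()
    sites["in_repeat"] = [
        bool(trees.get(c) and trees[c].overlaps_point(int(p)))
        for c, p in zip(sites["contig"], sites["pos"])
    ]
    return sites


def compare_repeat_vs_nonrepeat(
    sites: pd.DataFrame,
    n_downsample: int = N_DOWNSAMPLE,
    downsample_size: int | None = None,
    seed: int = 0,
    mode: str = "replicate",
) -> MethylationComparison:
    """Compare per-site frequencies between repeat and non-repeat sites.

    ``mode='replicate'`` (default): the two classes are balanced-downsampled
    ``n_downsample`` independent times and the two-sided rank-sum statistic
    and p-value are summarized by their medians across replicates.
    ``mode='fold_reduction'``: a single test on one subsample of size
    n/``n_downsample`` per class (the alternative reading of repeated
    downsampling as a plain size reduction).
    """
    if "in_repeat" not in sites.columns:
        raise ValueError("sites need an in_repeat column (see annotate_repeats)")
    rep = sites.loc[sites.in_repeat, "frequency"].to_numpy()
    non = sites.loc[~sites.in_repeat, "frequency"].to_numpy()
    if rep.size == 0 or non.size == 0:
        raise ValueError("both repeat and non-repeat classes must be non-empty")
    rng = np.random.default_rng(seed)

    if mode == "replicate":
        size = downsample_size or max(2, int(0.8 * min(rep.size, non.size)))
        size = min(size, rep.size, non.size)
        stats_, ps = [], []
        for _ in range(n_downsample):
            r = rng.choice(rep, size=size, replace=False)
            s = rng.choice(non, size=size, replace=False)
            res = stats.ranksums(r, s)
            stats_.append(res.statistic)
            ps.append(res.pvalue)
        statistic = float(np.median(stats_))
        p_value = float(np.median(ps))
        n_reps = n_downsample
    elif mode == "fold_reduction":
        size = max(2, min(rep.size, non.size) // n_downsample)
        r = rng.choice(rep, size=size, replace=False)
        s = rng.choice(non, size=size, replace=False)
        res = stats.ranksums(r, s)
        statistic, p_value = float(res.statistic), float(res.pvalue)
        n_reps = 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return MethylationComparison(
        mean_repeat=float(rep.mean()), mean_nonrepeat=float(non.mean()),
        statistic=statistic, p_value=p_value,
        n_repeat=int(rep.size), n_nonrepeat=int(non.size),
        n_downsample=n_reps, downsample_size=size)


def te_copy_methylation(
    sites: pd.DataFrame,
    copy_intervals: Sequence[tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Mean site frequency per annotated TE copy.

    ``copy_intervals`` rows are (copy_id, contig, start, end). Copies with no
    CpG site in range get NaN with a reason, rather than being dropped
    silently.
    """
    rows = []
    for copy_id, contig, start, end in copy_intervals:
        sel = sites[(sites.contig == contig) & (sites.pos >= start)
                    & (sites.pos < end)]
        if sel.empty:
            rows.append({"copy_id": copy_id, "mean_frequency": float("nan"),
                         "n_sites": 0, "note": "no CpG sites with calls"})
        else:
            rows.append({"copy_id": copy_id,
                         "mean_frequency": float(sel.frequency.mean()),
                         "n_sites": int(len(sel)), "note": "."})
    return pd.DataFrame(rows)
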