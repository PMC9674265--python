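"""Coverage-based TE family load and its variation across a population.

Per-sample read depth over each TE-family consensus is a proxy for copy
number. Depth is normalized to a 35x single-copy baseline, a family counts
as present only with >= 15x depth across >= 90% of the consensus (otherwise
its median is coded 0), and the coefficient of variation (SD/mean) of the
per-sample medians flags families with high load variation (above the third
quartile) as candidate active families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_COVERAGE = 35.0
MIN_DEPTH = 15.0
MIN_BREADTH = 0.90


@dataclass
class DepthProfile:
    """Per-position depth over each family consensus for one sample."""

    sample_id: str
    family_depths: dict[str, np.ndarray]
    observed_single_copy_median: float
    normalization_factor: float = field(init=False)

    def __post_init__(self) -> None:
        for fam, vec in self.family_depths.items():
            vec = np.asarray(vec, dtype=float)
            if vec.size == 0:
                raise ValueError(f"{fam}: empty depth vector")
            if (vec < 0).any():
                raise ValueError(f"{fam}: negative depths")
            self.family_depths[fam] = vec
        self.normalization_factor = normalization_factor(
            self.observed_single_copy_median)

    def normalized(self, family_id: str) -> np.ndarray:
        return self.family_depths[family_id] * self.normalization_factor


def normalization_factor(observed_single_copy_median: float,
                         target: float = TARGET_COVERAGE) -> float:
    """Multiplicative factor bringing single-copy coverage to ``target``.

    Mirrors read subsampling to 35x: subsampling can only reduce coverage,
    so the factor is capped at 1 (no upsampling) with a logged warning.
    """
    if observed_single_copy_median <= 0:
        raise ValueError("observed single-copy median must be positive")
    factor = target / observed_single_copy_median
    if factor > 1.0:
        logger.warning(
            "observed coverage %.1fx below the %.0fx target; capping the "
            "normalization factor at 1 (no upsampling)",
            observed_single_copy_median, target)
        factor = 1.0
    return factor


def family_presence_median(
    depth_vector: np.ndarray,
    min_depth: float = MIN_DEPTH,
    min_breadth: float = MIN_BREADTH,
) -> float:
    """Median depth of a family, or 0 when horizontal coverage is too low.

    Breadth is the fraction of consensus positions at or above ``min_depth``;
    below ``min_breadth`` the family is considered absent and coded 0. The
    median is taken over all consensus positions.
    """
    vec = np.asarray(depth_vector, dtype=float)
    if vec.size == 0:
        raise ValueError("empty depth vector")
    breadth = float((vec >= min_depth).mean())
    if breadth < min_breadth:
        return 0.0
    return float(np.median(vec))


def cv_across_samples(medians: Sequence[float]) -> float:
    """Coefficient of variation (sample SD / mean) of per-sample medians.

    Returns NaN (missing) when the mean is 0, i.e. the family is absent
    everywhere.
    """
    vals = np.asarray(medians, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two samples")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std(ddof=1) / mean)


def quartile_rank(cvs: Mapping[str, float]) -> dict[str, bool]:
    """Flag families whose CV lies strictly above the third quartile.

    Q3 uses linear interpolation (type-7); NaN CVs are excluded from the
    quantile and flagged False.
    """
    finite = {k: v for k, v in cvs.items() if np.isfinite(v)}
    if len(finite) < 4:
        raise ValueError("need at least four families with defined CV")
    q3 = float(np.quantile(list(finite.values()), 0.75))
    return {k: bool(np.isfinite(v) and v > q3) for k, v in cvs.items()}


def build_load_table(profiles: Sequence[DepthProfile],
                     min_depth: float = MIN_DEPTH,
                     min_breadth: float = MIN_BREADTH) -> pd.DataFrame:
    """Per-(sample, family) presence/median table with per-family CV and
    above-Q3 flag merged in."""
    if not profiles:
        raise ValueError("no depth profiles supplied")
    families = sorted({f for p in profiles for f in p.family_depths})
    rows = []
    for p in profiles:
        for fam in families:
            if fam not in p.family_depths:
                continue
            med = family_presence_median(p.normalized(fam), min_depth, min_breadth)
            rows.append({"sample_id": p.sample_id, "family_id": fam,
                         "median_depth": med, "present": med > 0})
    table = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cvs = {fam: cv_across_samples(
                   table.loc[table.family_id == fam, "median_depth"].to_numpy())
               for fam in families}
    flags = quartile_rank(cvs) if \
        sum(np.isfinite(v) for v in cvs.values()) >= 4 else \
        {fam: False for fam in families}
    table["cv"] = table["family_id"].map(cvs)
    table["above_q3"] = table["family_id"].map(flags)
    return table
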