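"""Nucleotide diversity (pi) from pileup base counts.

Per-site pi uses the unbiased pairwise-difference estimator: with column
depth n and allele frequencies p_b,

    pi = n/(n-1) * (1 - sum_b p_b^2)

which equals the fraction of differing unordered read pairs at the column.
Sites below a minimum depth are excluded; deletion-spanning reads do not
count toward depth (pi is defined over substitutions). Genome-level summaries
are the median and mean over qualifying sites, and groups of genome-level
values are compared with a two-sided Mann-Whitney U test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import BaseCountColumn


@dataclass
class DiversityProfile:
    ref_id: str
    per_site_pi: dict[int, float]   # position -> pi, qualifying sites only
    genome_pi_median: float | None
    genome_pi_mean: float | None
    n_sites: int
    min_depth: int


@dataclass
class PiComparison:
    u_statistic: float
    p_value: float
    fold_medians: float | None      # median(A) / median(B); None if undefined


def site_pi(column: BaseCountColumn, min_depth: int = 10) -> float | None:
    """Unbiased per-site pi, or None when depth < min_depth (or < 2)."""
    n = column.depth
    if n < max(min_depth, 2):
        return None
    sum_sq = sum(c * c for c in column.counts.values())
    return (n / (n - 1)) * (1.0 - sum_sq / (n * n))


def genome_pi(per_site: dict[int, float] | list[float]) -> tuple[float, float]:
    """Median and mean pi over qualifying sites.

    Raises ValueError when no sites qualify -- an explicit "not computable"
    outcome, never silently 0.
    """
    values = list(per_site.values()) if isinstance(per_site, dict) else list(per_site)
    values = [v for v in values if v is not None and not math.isnan(v)]
    if not values:
        raise ValueError("no qualifying sites: genome pi not computable")
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)), float(np.mean(arr))


def diversity_profile(
    columns: list[BaseCountColumn],
    ref_id: str,
    min_depth: int = 10,
) -> DiversityProfile:
    """Aggregate per-column pi values into a genome-level profile."""
    per_site: dict[int, float] = {}
    for col in columns:
        if col.ref_id != ref_id:
            continue
        pi = site_pi(col, min_depth)
        if pi is not None:
            per_site[col.pos] = pi
    if per_site:
        med, mean = genome_pi(per_site)
    else:
        med = mean = None
    return DiversityProfile(ref_id, per_site, med, mean, len(per_site), min_depth)


def compare_pi(group_a: list[float], group_b: list[float]) -> PiComparison:
    """Two-sided Mann-Whitney U comparison of genome-level pi values.

    U is reported for group A (number of (a, b) pairs with a > b, ties half);
    exact p-values for small tie-free samples, normal approximation with tie
    correction otherwise. The fold difference of medians is median(A) /
    median(B), undefined (None) when median(B) is zero.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(group_a, group_b, alternative="two-sided", method="auto")
    med_a = float(np.median(group_a))
    med_b = float(np.median(group_b))
    fold = med_a / med_b if med_b != 0 else None
    return PiComparison(float(res.statistic), float(res.pvalue), fold)
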