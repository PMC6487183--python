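"""Workflow evaluation statistics: chimera classification, indel accounting,
bootstrapped median effect sizes, breadth-filtered abundance, hypergeometric
enrichment and abundance correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .datamodel import AlignmentRecord


@dataclass
class ChimeraCall:
    read_id: str
    is_chimeric: bool
    evidence: list[tuple[str, tuple[int, int], str]]  # (ref, interval, strand)


@dataclass
class EffectSize:
    median_difference: float  # orientation fixed as A - B
    ci_low: float
    ci_high: float
    n_boot: int
    subsample: int


@dataclass
class AbundanceRow:
    contig_id: str
    mapped_reads: int
    breadth: float
    abundance: float


# ---------------------------------------------------------------------------
# chimeras
# ---------------------------------------------------------------------------

def chimera_classify(
    read_alignments: list[AlignmentRecord],
    max_gap_factor: float = 2.0,
    read_length: int | None = None,
    ref_lengths: dict[str, int] | None = None,
) -> ChimeraCall:
    """Classify one read as chimeric from all of its alignments.

    A read is chimeric when it has two or more non-colinear alignments:
    different references, a strand switch, or a same-reference gap larger
    than ``max_gap_factor`` times the read length. Split alignments that wrap
    a circular genome's origin (one block ending at the reference end, the
    other starting near zero) are colinear when ``ref_lengths`` is supplied,
    so circular fragments are not miscalled.
    """
    if not read_alignments:
        raise ValueError("need at least one alignment")
    read_id = read_alignments[0].read_id
    if any(a.read_id != read_id for a in read_alignments):
        raise ValueError("alignments belong to more than one read")
    evidence = [
        (a.ref_id, (a.ref_start, a.ref_end), a.strand) for a in read_alignments
    ]
    if len(read_alignments) == 1:
        return ChimeraCall(read_id, False, evidence)
    if read_length is None:
        read_length = max(a.read_end for a in read_alignments)
    max_gap = max_gap_factor * read_length

    def colinear(a: AlignmentRecord, b: AlignmentRecord) -> bool:
        if a.ref_id != b.ref_id or a.strand != b.strand:
            return False
        lo, hi = sorted([(a.ref_start, a.ref_end), (b.ref_start, b.ref_end)])
        gap = max(hi[0] - lo[1], 0)
        if gap <= max_gap:
            return True
        if ref_lengths is not None and a.ref_id in ref_lengths:
            wrap_gap = max(ref_lengths[a.ref_id] - hi[1], 0) + max(lo[0], 0)
            if wrap_gap <= max_gap:
                return True
        return False

    is_chimeric = any(
        not colinear(read_alignments[i], read_alignments[j])
        for i in range(len(read_alignments))
        for j in range(i + 1, len(read_alignments))
    )
    return ChimeraCall(read_id, is_chimeric, evidence)


def chimera_rate(
    alignments: list[AlignmentRecord],
    max_gap_factor: float = 2.0,
    read_lengths: dict[str, int] | None = None,
    ref_lengths: dict[str, int] | None = None,
) -> tuple[float, list[ChimeraCall]]:
    """Chimera rate over a read set: chimeric reads / total reads."""
    by_read: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
    calls = [
        chimera_classify(
            alns,
            max_gap_factor,
            read_lengths.get(rid) if read_lengths else None,
            ref_lengths,
        )
        for rid, alns in sorted(by_read.items())
    ]
    rate = sum(c.is_chimeric for c in calls) / len(calls)
    return rate, calls


# ---------------------------------------------------------------------------
# indel accounting
# ---------------------------------------------------------------------------

def indel_metrics(
    alignments: list[AlignmentRecord],
) -> tuple[int, int, float]:
    """Total insertions, deletions, and indels per 100 kbp of aligned reference."""
    if not alignments:
        raise ValueError("no alignments: indel rate undefined")
    ins = sum(a.insertions for a in alignments)
    dels = sum(a.deletions for a in alignments)
    span = sum(a.ref_span for a in alignments)
    if span == 0:
        raise ValueError("zero aligned reference bases: indel rate undefined")
    return ins, dels, (ins + dels) / span * 100_000


def fixed_indel_count(
    pre: list[AlignmentRecord], post: list[AlignmentRecord]
) -> int:
    """Number of indel errors fixed between two alignment sets of the same
    assembly (pre- vs post-polishing): difference of total indel counts."""
    pre_ins, pre_del, _ = indel_metrics(pre)
    post_ins, post_del, _ = indel_metrics(post)
    return (pre_ins + pre_del) - (post_ins + post_del)


# ---------------------------------------------------------------------------
# bootstrap median effect size
# ---------------------------------------------------------------------------

def bootstrap_median_diff(
    sample_a: list[float] | np.ndarray,
    sample_b: list[float] | np.ndarray,
    n_boot: int = 1000,
    subsample: int = 1000,
    seed: int = 0,
) -> EffectSize:
    """Bootstrapped median difference, orientation fixed as A - B.

    Per bootstrap, ``subsample`` values are drawn with replacement from each
    sample (capped at the sample size) and the difference of medians recorded;
    the effect size is the median of these differences with a 2.5/97.5
    percentile interval.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(seed)
    na = min(subsample, a.size)
    nb = min(subsample, b.size)
    med_a = np.median(a[rng.integers(0, a.size, size=(n_boot, na))], axis=1)
    med_b = np.median(b[rng.integers(0, b.size, size=(n_boot, nb))], axis=1)
    diffs = med_a - med_b
    return EffectSize(
        median_difference=float(np.median(diffs)),
        ci_low=float(np.percentile(diffs, 2.5)),
        ci_high=float(np.percentile(diffs, 97.5)),
        n_boot=n_boot,
        subsample=subsample,
    )


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def breadth_of_coverage(depth: np.ndarray) -> float:
    """Fraction of positions covered by at least one read."""
    depth = np.asarray(depth)
    return float(np.count_nonzero(depth) / depth.size)


def breadth_filter(
    rows: list[AbundanceRow], threshold: float = 0.40
) -> list[AbundanceRow]:
    """Zero the abundance of contigs with breadth strictly below threshold.

    The rule is 'less than': a contig at exactly the threshold is retained.
    """
    return [
        replace(r, abundance=0.0) if r.breadth < threshold else replace(r)
        for r in rows
    ]


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric enrichment p-value, P(X >= k).

    N: population size; K: successes in population; n: sample size;
    k: observed successes in sample.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def abundance_r2(
    estimated: list[float] | np.ndarray,
    truth: list[float] | np.ndarray,
    log_scale: bool = False,
    pseudocount: float = 1.0,
) -> float:
    """Squared Pearson correlation between estimated and true per-genome
    abundance values, optionally on log10(value + pseudocount)."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.size != tru.size or est.size < 3:
        raise ValueError("need matched vectors of at least 3 genomes")
    if log_scale:
        est = np.log10(est + pseudocount)
        tru = np.log10(tru + pseudocount)
    if np.std(est) == 0 or np.std(tru) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(est, tru)[0, 1])
    return r * r
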