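"""Read-recruitment pileups, sliding-window coverage statistics and
genomic-island calling at multiple read-identity cutoffs.

Islands are contig regions that under-recruit reads relative to the rest of
the genome: at a given mapping-identity cutoff, windows whose median depth
falls below a fraction ``alpha`` of the contig-level median window depth are
flagged and merged. Because island content diverges from the representative
contig, raising the identity cutoff removes more reads inside islands than
outside, so island extent grows (weakly) with the cutoff.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import AlignmentRecord, BaseCountColumn, ContigRecord, GenomicIsland

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Per-window statistic along one contig (fixed window/step grid)."""

    ref_id: str
    window: int
    step: int
    values: np.ndarray
    window_starts: np.ndarray
    contig_length: int

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError("require window >= step >= 1")


def pileup(
    alignments: list[AlignmentRecord],
    contig: ContigRecord,
    identity_cutoff: float = 0.0,
    reads: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[BaseCountColumn]]:
    """Depth vector (and optional base counts) from reads recruited at
    >= ``identity_cutoff`` overall alignment identity.

    Reads are assigned whole to an identity class by their overall alignment
    identity, as a read mapper's identity filter would. Depth counts reference
    positions covered by contributing alignments (read insertions do not add
    depth). When ``reads`` maps read id -> sequence, per-column base counts
    are computed by re-aligning each recruited read segment to its reference
    interval (edlib); deletion-spanning columns increment ``del_count``
    instead of a base count.
    """
    L = len(contig)
    depth = np.zeros(L, dtype=np.int64)
    kept = [
        a
        for a in alignments
        if a.ref_id == contig.id and a.identity >= identity_cutoff
    ]
    for aln in kept:
        if aln.ref_end > L:
            raise ValueError(
                f"{aln.read_id}: alignment end {aln.ref_end} > contig length {L}"
            )
        depth[aln.ref_start : aln.ref_end] += 1

    columns: list[BaseCountColumn] = []
    if reads is not None:
        base_counts = np.zeros((L, 4), dtype=np.int64)
        del_counts = np.zeros(L, dtype=np.int64)
        for aln in kept:
            seq = reads.get(aln.read_id)
            if seq is None:
                continue
            _accumulate_columns(aln, seq, contig.seq, base_counts, del_counts)
        covered = np.nonzero(base_counts.sum(axis=1) + del_counts)[0]
        for pos in covered:
            counts = {
                b: int(c)
                for b, c in zip("ACGT", base_counts[pos])
                if c > 0
            }
            columns.append(
                BaseCountColumn(contig.id, int(pos), counts, int(del_counts[pos]))
            )
    return depth, columns


_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}


def _accumulate_columns(
    aln: AlignmentRecord,
    read_seq: str,
    ref_seq: str,
    base_counts: np.ndarray,
    del_counts: np.ndarray,
) -> None:
    import edlib

    from .datamodel import revcomp

    seg = read_seq[aln.read_start : aln.read_end]
    if aln.strand == "-":
        seg = revcomp(seg)
    ref_sub = ref_seq[aln.ref_start : aln.ref_end]
    if aln.insertions == 0 and aln.deletions == 0 and len(seg) == len(ref_sub):
        # gapless: direct column-wise accumulation
        codes = np.frombuffer(seg.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int64)
        for b, i in _B2I.items():
            lut[ord(b)] = i
        idx = lut[codes]
        valid = idx >= 0
        pos = np.arange(aln.ref_start, aln.ref_end)[valid]
        base_counts[pos, idx[valid]] += 1
        return
    res = edlib.align(seg, ref_sub, task="path", mode="NW")
    ref_pos = aln.ref_start
    read_pos = 0
    for n, op in _iter_cigar(res["cigar"]):
        if op in ("=", "X", "M"):
            for j in range(n):
                b = seg[read_pos + j]
                if b in _B2I:
                    base_counts[ref_pos + j, _B2I[b]] += 1
            ref_pos += n
            read_pos += n
        elif op == "I":
            read_pos += n
        elif op == "D":
            del_counts[ref_pos : ref_pos + n] += 1
            ref_pos += n


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def windowed_stat(
    vector: np.ndarray,
    ref_id: str = "",
    window: int = 200,
    step: int = 100,
    stat: str = "median",
) -> CoverageProfile:
    """Sliding-window summary (median or max) of a per-base vector."""
    if stat not in ("median", "max"):
        raise ValueError(f"unsupported stat {stat!r}")
    vector = np.asarray(vector, dtype=float)
    L = vector.size
    if L < window:
        logger.warning(
            "%s: contig length %d < window %d; using one whole-contig window",
            ref_id,
            L,
            window,
        )
        fn = np.median if stat == "median" else np.max
        return CoverageProfile(
            ref_id, window, step, np.array([fn(vector)]), np.array([0]), L
        )
    starts = np.arange(0, L - window + 1, step)
    idx = starts[:, None] + np.arange(window)[None, :]
    windows = vector[idx]
    values = np.median(windows, axis=1) if stat == "median" else windows.max(axis=1)
    return CoverageProfile(ref_id, window, step, values, starts, L)


def call_islands(
    profile: CoverageProfile,
    alpha: float = 0.2,
    min_len: int = 200,
    identity_cutoff: float = 0.0,
    depth: np.ndarray | None = None,
) -> list[GenomicIsland]:
    """Call under-recruiting intervals from a windowed median-depth profile.

    Windows with value below ``alpha`` times the contig-level median of window
    values are flagged; overlapping or abutting flagged windows merge into
    islands; islands shorter than ``min_len`` are discarded. Mean within-island
    depth comes from ``depth`` when given, else from overlapping window values.
    """
    contig_median = float(np.median(profile.values))
    if contig_median == 0.0:
        logger.warning(
            "%s: all-zero coverage profile; whole contig flagged as degenerate",
            profile.ref_id,
        )
        return [
            GenomicIsland(
                profile.ref_id, 0, profile.contig_length, identity_cutoff, 0.0, 0.0
            )
        ]
    flagged = profile.values < alpha * contig_median
    islands: list[GenomicIsland] = []
    i = 0
    n = flagged.size
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        start = int(profile.window_starts[i])
        end = int(profile.window_starts[i]) + profile.window
        j = i + 1
        while j < n and flagged[j] and int(profile.window_starts[j]) <= end:
            end = int(profile.window_starts[j]) + profile.window
            j += 1
        if end - start >= min_len:
            if depth is not None:
                mean_cov = float(np.mean(depth[start:end]))
            else:
                sel = (profile.window_starts < end) & (
                    profile.window_starts + profile.window > start
                )
                mean_cov = float(np.mean(profile.values[sel]))
            islands.append(
                GenomicIsland(
                    profile.ref_id, start, end, identity_cutoff, mean_cov, contig_median
                )
            )
        i = j
    return islands


def island_metrics(
    islands: list[GenomicIsland], contig_len: int
) -> tuple[list[int], float]:
    """Island lengths and density (bp of island per kbp of genome)."""
    if islands:
        refs = {isl.ref_id for isl in islands}
        cuts = {isl.identity_cutoff for isl in islands}
        if len(refs) > 1 or len(cuts) > 1:
            raise ValueError("islands must share one contig and one cutoff")
    lengths = [len(isl) for isl in islands]
    density = sum(lengths) / (contig_len / 1000.0)
    return lengths, density
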