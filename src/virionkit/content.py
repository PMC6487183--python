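"""Island content analysis from spanning long reads.

A long read reveals the content of a genomic island when it is anchored on
the island's flanks: full-span reads cover the island plus a border on each
side; anchored reads cover one flank and extend a minimum distance into the
island. ORFs called on spanning reads are projected to contig coordinates,
clustered into consensus gene loci, and compared across reads to detect
alternative gene arrangements within the population.
"""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

from .datamodel import AlignmentRecord, GenomicIsland, revcomp

logger = logging.getLogger(__name__)


@dataclass
class SpanningReadSet:
    island: GenomicIsland
    full_span_reads: list[str]
    anchored_reads: list[str]
    border: int = 100
    min_ext: int = 1000


@dataclass
class OrfCall:
    """An open reading frame (ATG..stop) on the forward coordinates of a
    sequence; ``aa_length`` counts residues excluding the stop codon."""

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_length: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


@dataclass
class Locus:
    start: int
    end: int
    support: int
    members: list[tuple[str, int]] = field(default_factory=list)  # (read, orf idx)


@dataclass
class IslandContentReport:
    island: GenomicIsland
    loci: list[Locus]
    signatures: dict[str, tuple[int, ...]]  # read -> presence vector over loci
    n_distinct_arrangements: int
    alternative_arrangement: bool | None    # None = not assessable (<2 reads)


# ---------------------------------------------------------------------------
# spanning-read classification
# ---------------------------------------------------------------------------

def classify_spanning_reads(
    alignments: list[AlignmentRecord],
    island: GenomicIsland,
    border: int = 100,
    min_ext: int = 1000,
    contig_length: int | None = None,
) -> SpanningReadSet:
    """Classify reads as full-span or anchored relative to one island.

    A read is full-span when its aligned reference interval covers
    ``[start - border, end + border)``; anchored when it covers at least
    ``border`` bp outside one boundary and extends at least ``min_ext``
    (capped at the island length) into the island. Full-span takes
    precedence. Flanks are truncated at contig bounds (with a warning) when
    the island sits within ``border`` bp of a contig end.
    """
    left = island.start - border
    right = island.end + border
    if left < 0 or (contig_length is not None and right > contig_length):
        logger.warning(
            "island [%d,%d) on %s lies within %d bp of a contig end; "
            "flanks truncated",
            island.start,
            island.end,
            island.ref_id,
            border,
        )
        left = max(left, 0)
        if contig_length is not None:
            right = min(right, contig_length)
    ext = min(min_ext, island.end - island.start)

    spans: dict[str, tuple[int, int]] = {}
    for aln in alignments:
        if aln.ref_id != island.ref_id:
            continue
        cur = spans.get(aln.read_id)
        if cur is None:
            spans[aln.read_id] = (aln.ref_start, aln.ref_end)
        else:
            spans[aln.read_id] = (min(cur[0], aln.ref_start), max(cur[1], aln.ref_end))

    full, anchored = [], []
    for read_id, (s, e) in sorted(spans.items()):
        if s <= left and e >= right:
            full.append(read_id)
        elif s <= left and e >= island.start + ext:
            anchored.append(read_id)
        elif e >= right and s <= island.end - ext:
            anchored.append(read_id)
    return SpanningReadSet(island, full, anchored, border, min_ext)


# ---------------------------------------------------------------------------
# ORF calling (deliberately simple stand-in gene caller)
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def _scan_forward(seq: str, seq_id: str, strand: str, L: int, min_aa: int) -> list[OrfCall]:
    calls = []
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in _STOPS and start is not None:
                end = i + 3
                aa = (end - start) // 3 - 1
                if aa >= min_aa:
                    if strand == "+":
                        calls.append(OrfCall(seq_id, start, end, "+", frame, aa))
                    else:
                        calls.append(OrfCall(seq_id, L - end, L - start, "-", frame, aa))
                start = None
    return calls


def call_orfs(seq: str, min_aa: int = 30, seq_id: str = "") -> list[OrfCall]:
    """Six-frame ORF scan: ATG..stop, longest ORF per stop, >= min_aa residues.

    Used for *comparative* protein-length analyses (the same caller on all
    inputs); it is not a gene-model predictor. Coordinates are on the forward
    sequence; reverse-strand calls carry strand '-'.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    calls = _scan_forward(seq, seq_id, "+", len(seq), min_aa)
    calls += _scan_forward(revcomp(seq), seq_id, "-", len(seq), min_aa)
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


# ---------------------------------------------------------------------------
# coordinate projection and consensus loci
# ---------------------------------------------------------------------------

def project_interval(
    aln: AlignmentRecord, start: int, end: int
) -> tuple[int, int]:
    """Project a read-coordinate interval to contig coordinates through the
    read's alignment, linearly between the alignment's endpoints (robust to
    indels without per-base liftover)."""
    read_span = aln.read_end - aln.read_start
    scale = aln.ref_span / read_span
    if aln.strand == "+":
        lo = aln.ref_start + (start - aln.read_start) * scale
        hi = aln.ref_start + (end - aln.read_start) * scale
    else:
        lo = aln.ref_start + (aln.read_end - end) * scale
        hi = aln.ref_start + (aln.read_end - start) * scale
    return int(round(lo)), int(round(hi))


def consensus_loci(
    orfs_by_read: dict[str, list[tuple[int, int]]],
    tol: int = 50,
) -> list[Locus]:
    """Single-linkage clustering of contig-projected ORF intervals.

    Two ORFs link when both boundary differences are within ``tol`` bp; each
    cluster becomes a locus at the median boundaries, supported by the number
    of distinct reads contributing to it.
    """
    items: list[tuple[str, int, int, int]] = []  # (read, idx, start, end)
    for read_id in sorted(orfs_by_read):
        for i, (s, e) in enumerate(orfs_by_read[read_id]):
            items.append((read_id, i, s, e))
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(items[i][2] - items[j][2]) <= tol
                and abs(items[i][3] - items[j][3]) <= tol
            ):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    loci = []
    for members in groups.values():
        starts = [items[i][2] for i in members]
        ends = [items[i][3] for i in members]
        reads = {items[i][0] for i in members}
        loci.append(
            Locus(
                start=int(statistics.median(starts)),
                end=int(statistics.median(ends)),
                support=len(reads),
                members=[(items[i][0], items[i][1]) for i in members],
            )
        )
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


def arrangement_report(
    island: GenomicIsland,
    spanning: SpanningReadSet,
    loci: list[Locus],
    min_support: int = 2,
) -> IslandContentReport:
    """Detect alternative gene arrangements across full-span reads.

    Each full-span read gets an ordered presence vector over the consensus
    loci; the island shows alternative arrangements when at least two distinct
    vectors are each supported by >= ``min_support`` reads. With fewer than
    two full-span reads the question is not assessable (``None``).
    """
    membership: list[set[str]] = [
        {read for read, _ in locus.members} for locus in loci
    ]
    signatures: dict[str, tuple[int, ...]] = {}
    for read_id in spanning.full_span_reads:
        signatures[read_id] = tuple(
            1 if read_id in reads else 0 for reads in membership
        )
    counts: dict[tuple[int, ...], int] = {}
    for sig in signatures.values():
        counts[sig] = counts.get(sig, 0) + 1
    n_distinct = max(len(counts), 1)
    if len(signatures) < 2:
        alternative: bool | None = None
    else:
        alternative = sum(1 for c in counts.values() if c >= min_support) >= 2
    return IslandContentReport(island, loci, signatures, n_distinct, alternative)
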