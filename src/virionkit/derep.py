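"""Dereplication of contigs into viral populations by average nucleotide
identity (ANI), following the standard viral-population convention: contigs
cluster together at >= 95% ANI over >= 80% of the length of the shorter
contig, and the longest member represents each population.

ANI values come from caller-supplied alignment blocks (whole-genome alignment
is external); a small exact-k-mer-anchored block finder is provided for test
fixtures only.
"""
from __future__ import annotations

from dataclasses import dataclass

from .datamodel import AlignmentRecord, ContigRecord


@dataclass
class AniEstimate:
    """Pairwise ANI summary between two contigs.

    ``ani`` is the length-weighted mean identity over aligned blocks;
    ``aligned_fraction`` is the fraction of the shorter contig covered by the
    union of block spans.
    """

    query_id: str
    target_id: str
    ani: float
    aligned_fraction: float


@dataclass
class PopulationCluster:
    representative_id: str
    member_ids: list[str]
    ani_min: float
    cov_min: float


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    prev_end = -1
    for start, end in sorted(intervals):
        start = max(start, prev_end)
        if end > start:
            total += end - start
            prev_end = end
        prev_end = max(prev_end, end)
    return total


def block_ani(
    blocks: list[AlignmentRecord], len_query: int, len_target: int
) -> AniEstimate:
    """Summarise alignment blocks between one contig pair into an ANI estimate.

    ANI is the mean block identity weighted by reference span; the aligned
    fraction is measured on the shorter of the two contigs (overlapping blocks
    counted once). An empty block set yields ani=0, aligned_fraction=0.
    """
    if not blocks:
        return AniEstimate("", "", 0.0, 0.0)
    qids = {b.read_id for b in blocks}
    tids = {b.ref_id for b in blocks}
    if len(qids) != 1 or len(tids) != 1:
        raise ValueError("blocks mix more than one contig pair")
    query_id, target_id = qids.pop(), tids.pop()
    total_span = sum(b.ref_span for b in blocks)
    ani = sum(b.identity * b.ref_span for b in blocks) / total_span
    shorter = min(len_query, len_target)
    if len_query <= len_target:
        intervals = [(b.read_start, b.read_end) for b in blocks]
    else:
        intervals = [(b.ref_start, b.ref_end) for b in blocks]
    frac = min(_interval_union(intervals) / shorter, 1.0)
    return AniEstimate(query_id, target_id, ani, frac)


def dereplicate(
    contigs: list[ContigRecord],
    ani_table: list[AniEstimate],
    ani_min: float = 0.95,
    cov_min: float = 0.80,
) -> list[PopulationCluster]:
    """Greedy star clustering of contigs into populations.

    Contigs are visited longest-first (ties broken by id); each joins the
    first existing cluster whose *representative* it matches at
    ``ani >= ani_min`` and ``aligned_fraction >= cov_min``, else founds a new
    cluster. Pairs absent from ``ani_table`` are treated as below threshold.
    """
    ids = {c.id for c in contigs}
    pair: dict[tuple[str, str], AniEstimate] = {}
    for est in ani_table:
        if est.query_id not in ids or est.target_id not in ids:
            raise ValueError(
                f"ani_table references unknown contig "
                f"{est.query_id!r}/{est.target_id!r}"
            )
        key = (min(est.query_id, est.target_id), max(est.query_id, est.target_id))
        pair[key] = est

    order = sorted(contigs, key=lambda c: (-len(c), c.id))
    clusters: list[PopulationCluster] = []
    for contig in order:
        placed = False
        for cl in clusters:
            key = (
                min(contig.id, cl.representative_id),
                max(contig.id, cl.representative_id),
            )
            est = pair.get(key)
            if est is not None and est.ani >= ani_min and est.aligned_fraction >= cov_min:
                cl.member_ids.append(contig.id)
                placed = True
                break
        if not placed:
            clusters.append(PopulationCluster(contig.id, [contig.id], ani_min, cov_min))
    return clusters


# ---------------------------------------------------------------------------
# fixture-grade block finder (exact k-mer anchors, ungapped X-drop extension)
# ---------------------------------------------------------------------------

def find_alignment_blocks(
    query: ContigRecord,
    target: ContigRecord,
    k: int = 21,
    xdrop: int = 20,
) -> list[AlignmentRecord]:
    """Ungapped alignment blocks between two contigs, anchored on exact
    k-mer matches and extended with an X-drop rule (+1 match / -2 mismatch).

    This is a test-fixture utility, not a production aligner: it finds
    forward-strand, ungapped blocks only.
    """
    tq, tt = query.seq, target.seq
    anchors: dict[str, list[int]] = {}
    for i in range(len(tt) - k + 1):
        anchors.setdefault(tt[i : i + k], []).append(i)

    covered: dict[int, int] = {}  # diagonal -> rightmost query end already extended
    blocks: list[AlignmentRecord] = []
    for qi in range(len(tq) - k + 1):
        kmer = tq[qi : qi + k]
        for ti in anchors.get(kmer, ()):
            diag = qi - ti
            if covered.get(diag, -1) >= qi + k:
                continue  # anchor already inside a block on this diagonal
            # extend left
            ql, tl = qi, ti
            score = best = 0
            best_l = 0
            off = 0
            while ql - off - 1 >= 0 and tl - off - 1 >= 0:
                off += 1
                score += 1 if tq[ql - off] == tt[tl - off] else -2
                if score > best:
                    best, best_l = score, off
                if best - score > xdrop:
                    break
            # extend right
            qr, tr = qi + k, ti + k
            score = best = 0
            best_r = 0
            off = 0
            while qr + off < len(tq) and tr + off < len(tt):
                score += 1 if tq[qr + off] == tt[tr + off] else -2
                off += 1
                if score > best:
                    best, best_r = score, off
                if best - score > xdrop:
                    break
            qs, qe = ql - best_l, qr + best_r
            if covered.get(diag, -1) >= qe:
                continue
            covered[diag] = qe
            ts_, te_ = qs - diag, qe - diag
            n = qe - qs
            matches = sum(1 for a, b in zip(tq[qs:qe], tt[ts_:te_]) if a == b)
            blocks.append(
                AlignmentRecord(
                    read_id=query.id,
                    ref_id=target.id,
                    ref_start=ts_,
                    ref_end=te_,
                    read_start=qs,
                    read_end=qe,
                    strand="+",
                    matches=matches,
                    mismatches=n - matches,
                )
            )
    # keep maximal blocks per diagonal (drop blocks contained in another on the
    # same diagonal)
    blocks.sort(key=lambda b: (b.read_start - b.ref_start, b.read_start, -b.read_end))
    kept: list[AlignmentRecord] = []
    for b in blocks:
        if (
            kept
            and kept[-1].read_start - kept[-1].ref_start == b.read_start - b.ref_start
            and b.read_end <= kept[-1].read_end
        ):
            continue
        kept.append(b)
    return kept
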