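"""Readers and writers for FASTA/FASTQ, PAF, SAM-subset and island BED files.

FASTA/FASTQ go through Biopython; SAM text goes through pysam. PAF carries the
12 mandatory columns plus optional NM:i (edit distance) and cg:Z (CIGAR) tags,
which are used to split edit operations when present.
"""
from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Sequence
from pathlib import Path

from Bio import SeqIO

from .datamodel import (
    AlignmentRecord,
    ContigRecord,
    GenomicIsland,
    ReadRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class ParseError(ValueError):
    """Raised on malformed input, naming the offending location."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path, format: str = "fasta") -> list[ContigRecord]:
    """Read FASTA or FASTQ into ContigRecords (uppercased, order preserved).

    Duplicate ids raise :class:`ValidationError`; malformed records raise
    :class:`ParseError`.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    records: list[ContigRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), format):
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(ContigRecord(rec.id, str(rec.seq).upper()))
    except ValueError as exc:  # Biopython signals malformed records this way
        if isinstance(exc, (ValidationError, ParseError)):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return reads


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _cigar_counts(cigar: str) -> tuple[int, int, int, int, int]:
    """Return (aligned_M, eq, x, ins, del) column counts from a CIGAR string."""
    m = eq = x = ins = dels = 0
    pos = 0
    for match in _CIGAR_RE.finditer(cigar):
        n, op = int(match.group(1)), match.group(2)
        pos = match.end()
        if op == "M":
            m += n
        elif op == "=":
            eq += n
        elif op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op in ("D", "N"):
            dels += n
        # S/H/P consume no alignment columns we account for
    if pos != len(cigar):
        raise ParseError(f"malformed CIGAR {cigar!r}")
    return m, eq, x, ins, dels


def _record_from_paf_fields(fields: list[str], lineno: int, path) -> AlignmentRecord | None:
    if len(fields) < 12:
        raise ParseError(f"{path}:{lineno}: PAF line has {len(fields)} < 12 columns")
    qname, qlen, qstart, qend, strand = fields[0], int(fields[1]), int(fields[2]), int(fields[3]), fields[4]
    tname, tlen, tstart, tend = fields[5], int(fields[6]), int(fields[7]), int(fields[8])
    nmatch, blocklen = int(fields[9]), int(fields[10])
    if tname == "*":
        return None
    if tend > tlen:
        raise ValidationError(
            f"{path}:{lineno}: alignment end {tend} exceeds target length {tlen}"
        )
    if qend > qlen:
        raise ValidationError(
            f"{path}:{lineno}: read end {qend} exceeds read length {qlen}"
        )
    nm = None
    cigar = None
    is_primary = True
    for tag in fields[12:]:
        if tag.startswith("NM:i:"):
            nm = int(tag[5:])
        elif tag.startswith("cg:Z:"):
            cigar = tag[5:]
        elif tag.startswith("tp:A:"):
            is_primary = tag[5:] == "P"
    if cigar is not None:
        m, eq, x, ins, dels = _cigar_counts(cigar)
        if eq or x:
            matches, mismatches = eq, x
            if m:  # mixed M with =/X: treat M as matches
                matches += m
        elif nm is not None:
            mismatches = max(nm - ins - dels, 0)
            matches = m - mismatches
        else:
            matches, mismatches = nmatch, m - nmatch
    else:
        ins = dels = 0
        if nm is not None:
            mismatches = nm
            matches = blocklen - mismatches
        else:
            matches = nmatch
            mismatches = blocklen - nmatch
    return AlignmentRecord(
        read_id=qname,
        ref_id=tname,
        ref_start=tstart,
        ref_end=tend,
        read_start=qstart,
        read_end=qend,
        strand=strand,
        matches=matches,
        mismatches=mismatches,
        insertions=ins,
        deletions=dels,
        is_primary=is_primary,
    )


def _read_paf(path: str | Path) -> list[AlignmentRecord]:
    records = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rec = _record_from_paf_fields(line.split("\t"), lineno, path)
            if rec is None:
                skipped += 1
            else:
                records.append(rec)
    if skipped:
        logger.info("%s: skipped %d unmapped records", path, skipped)
    return records


def _read_sam(path: str | Path, ref_lengths: dict[str, int] | None) -> list[AlignmentRecord]:
    import pysam

    records = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                skipped += 1
                continue
            if aln.cigartuples is None:
                raise ParseError(
                    f"{path}: read {aln.query_name!r} mapped but has no CIGAR"
                )
            m = eq = x = ins = dels = 0
            for op, n in aln.cigartuples:
                if op == 0:
                    m += n
                elif op == 7:
                    eq += n
                elif op == 8:
                    x += n
                elif op == 1:
                    ins += n
                elif op in (2, 3):
                    dels += n
            if eq or x:
                matches, mismatches = eq + m, x
            elif aln.has_tag("NM"):
                nm = aln.get_tag("NM")
                mismatches = max(nm - ins - dels, 0)
                matches = m - mismatches
            else:
                matches, mismatches = m, 0
            ref_id = aln.reference_name
            ref_end = aln.reference_end
            if ref_lengths is not None and ref_id in ref_lengths:
                if ref_end > ref_lengths[ref_id]:
                    raise ValidationError(
                        f"{path}: {aln.query_name} ends at {ref_end} > "
                        f"reference length {ref_lengths[ref_id]}"
                    )
            qstart = aln.query_alignment_start
            qend = aln.query_alignment_end
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=ref_id,
                    ref_start=aln.reference_start,
                    ref_end=ref_end,
                    read_start=qstart,
                    read_end=qend,
                    strand="-" if aln.is_reverse else "+",
                    matches=matches,
                    mismatches=mismatches,
                    insertions=ins,
                    deletions=dels,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                )
            )
    if skipped:
        logger.info("%s: skipped %d unmapped records", path, skipped)
    return records


def read_alignments(
    path: str | Path,
    dialect: str = "paf",
    ref_lengths: dict[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Read PAF or SAM-subset alignments into internal 0-based half-open records.

    Unmapped records are skipped with a logged count. When ``ref_lengths`` is
    supplied, coordinates are validated against it (PAF carries target lengths
    inline and is always validated).
    """
    if dialect == "paf":
        records = _read_paf(path)
        if ref_lengths is not None:
            for rec in records:
                if rec.ref_id in ref_lengths and rec.ref_end > ref_lengths[rec.ref_id]:
                    raise ValidationError(
                        f"{rec.read_id}: end {rec.ref_end} > reference length "
                        f"{ref_lengths[rec.ref_id]}"
                    )
        return records
    if dialect in ("sam", "sam-subset"):
        return _read_sam(path, ref_lengths)
    raise ValueError(f"unsupported alignment dialect {dialect!r}")


def write_paf(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    read_lengths: dict[str, int],
    ref_lengths: dict[str, int],
) -> None:
    """Write alignments as PAF with NM:i and a coarse cg:Z tag.

    The emitted CIGAR pools matches and mismatches into one M run; together
    with NM the original edit counts round-trip exactly.
    """
    with open(path, "w") as fh:
        for rec in records:
            nm = rec.mismatches + rec.insertions + rec.deletions
            cg = f"{rec.matches + rec.mismatches}M"
            if rec.insertions:
                cg += f"{rec.insertions}I"
            if rec.deletions:
                cg += f"{rec.deletions}D"
            fields = [
                rec.read_id,
                str(read_lengths[rec.read_id]),
                str(rec.read_start),
                str(rec.read_end),
                rec.strand,
                rec.ref_id,
                str(ref_lengths[rec.ref_id]),
                str(rec.ref_start),
                str(rec.ref_end),
                str(rec.matches),
                str(rec.matches + rec.mismatches + rec.insertions + rec.deletions),
                "255",
                f"NM:i:{nm}",
                f"cg:Z:{cg}",
                f"tp:A:{'P' if rec.is_primary else 'S'}",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# islands (BED3+)
# ---------------------------------------------------------------------------

_BED_HEADER = "#ref\tstart\tend\tidentity_cutoff\tmean_cov\tcontig_median_cov"


def write_islands_bed(islands: Sequence[GenomicIsland], path: str | Path) -> None:
    """Write islands as BED3+ sorted by (contig, start).

    Overlapping islands on one contig at one identity cutoff indicate a
    merging bug upstream and raise :class:`ValidationError`.
    """
    ordered = sorted(islands, key=lambda g: (g.ref_id, g.identity_cutoff, g.start))
    prev: GenomicIsland | None = None
    for isl in ordered:
        if (
            prev is not None
            and isl.ref_id == prev.ref_id
            and isl.identity_cutoff == prev.identity_cutoff
            and isl.start < prev.end
        ):
            raise ValidationError(
                f"overlapping islands on {isl.ref_id} at cutoff "
                f"{isl.identity_cutoff}: [{prev.start},{prev.end}) and "
                f"[{isl.start},{isl.end})"
            )
        prev = isl
    ordered.sort(key=lambda g: (g.ref_id, g.start, g.identity_cutoff))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for isl in ordered:
            fh.write(
                f"{isl.ref_id}\t{isl.start}\t{isl.end}\t"
                f"{isl.identity_cutoff:g}\t{isl.mean_cov:.6g}\t"
                f"{isl.contig_median_cov:.6g}\n"
            )


def read_islands_bed(path: str | Path) -> list[GenomicIsland]:
    islands = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            islands.append(
                GenomicIsland(
                    ref_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    identity_cutoff=float(fields[3]),
                    mean_cov=float(fields[4]),
                    contig_median_cov=float(fields[5]),
                )
            )
    return islands
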