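"""Core domain types shared by every stage of the toolkit.

All coordinates are 0-based half-open throughout the package; BED output is
native to this convention and human-readable reports convert to 1-based
inclusive at the formatting boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass
class ContigRecord:
    """A named nucleotide sequence; the unit of assembly/population analysis.

    ``circular`` marks contigs with matching ends, the standard proxy for a
    completely assembled viral genome.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise ValidationError(f"contig {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValidationError(
                f"contig {self.id!r}: invalid bases {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """A sequencing read with an optional constant-quality string."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValidationError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """One read-to-contig (or contig-to-contig) alignment block.

    Reverse-strand alignments keep read coordinates on the forward read; the
    strand flag carries orientation (PAF semantics). ``insertions`` counts
    bases present in the read but absent from the reference; ``deletions``
    the converse.
    """

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    matches: int
    mismatches: int
    insertions: int = 0
    deletions: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.ref_start < self.ref_end):
            raise ValidationError(
                f"{self.read_id}->{self.ref_id}: bad reference interval "
                f"[{self.ref_start},{self.ref_end})"
            )
        if not (0 <= self.read_start < self.read_end):
            raise ValidationError(
                f"{self.read_id}: bad read interval "
                f"[{self.read_start},{self.read_end})"
            )
        for name in ("matches", "mismatches", "insertions", "deletions"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.read_id}: negative {name}")

    @property
    def identity(self) -> float:
        """Fraction of alignment columns that match: m / (m + mm + ins + del)."""
        denom = self.matches + self.mismatches + self.insertions + self.deletions
        if denom == 0:
            return 0.0
        return self.matches / denom

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class BaseCountColumn:
    """Per-position base counts from a pileup; substrate for diversity."""

    ref_id: str
    pos: int
    counts: dict[str, int] = field(default_factory=dict)
    del_count: int = 0

    def __post_init__(self) -> None:
        for base, c in self.counts.items():
            if base not in "ACGT":
                raise ValidationError(f"bad base {base!r} in counts")
            if c < 0:
                raise ValidationError("negative base count")
        if self.del_count < 0:
            raise ValidationError("negative deletion count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenomicIsland:
    """An under-recruiting interval on a contig at a given identity cutoff."""

    ref_id: str
    start: int
    end: int
    identity_cutoff: float
    mean_cov: float
    contig_median_cov: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"island on {self.ref_id}: bad interval [{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]
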