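"""Mock viral community simulator with full ground truth.

Emulates the data-generating process of a linker-amplified long-read (LASL)
virome plus complementary short-read sequencing of the same DNA pool:

* a small community of phage-sized genomes pooled at given particle counts,
  with reads sampled in proportion to DNA mass (particles x genome length);
* shearing to ~8 kbp with preferential PCR amplification of shorter
  fragments, so the emitted read-length median falls well below the shear
  target;
* indel-dominated long-read errors and substitution-only short-read errors;
* a small fraction of chimeric long reads formed by joining two independent
  fragments during amplification;
* microdiverse strain clouds around each genome with a calibrated nucleotide
  diversity (pi), and planted variable genomic islands whose cassette content
  differs between strains.

Every read carries ground truth (origin strain, origin interval(s), chimera
flag), and truth alignments are emitted directly so no external aligner is
needed to test downstream stages.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datamodel import AlignmentRecord, ContigRecord, ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 0  # N treated as A inside the simulator (never emitted)

LONG_QUAL_CHAR = chr(10 + 33)   # constant Q10 for long reads
SHORT_QUAL_CHAR = chr(30 + 33)  # constant Q30 for short reads

# pi saturates at 0.75 under the uniform-alternate-base mutation model
PI_SATURATION = 0.75


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


# ---------------------------------------------------------------------------
# parameters & truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Study conditions for the mock community.

    Defaults mirror the mock-community conditions the toolkit is built to
    emulate: six Caudovirales-sized genomes (38.5-129.4 kbp) pooled at equal
    particle counts, ~8 kbp shearing with PCR length bias calibrated so the
    emitted median read length is about half the shear target, 8% total
    long-read error of which 60% are indels, 2 x 300 bp short pairs at 0.5%
    substitution error, and a 0.95% chimera rate.
    """

    n_genomes: int = 6
    genome_length_range: tuple[int, int] = (38_500, 129_400)
    relative_particle_abundances: tuple[float, ...] | None = None
    gc: float = 0.45
    shear_mean: float = 8_000.0
    shear_sigma: float = 0.55
    pcr_bias_scale: float = 2_500.0
    min_fragment: int = 500
    long_error_total: float = 0.08
    long_indel_fraction: float = 0.6
    short_error_total: float = 0.005
    short_read_length: int = 300
    insert_mean: float = 700.0
    insert_sd: float = 60.0
    chimera_rate: float = 0.0095
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "long_error_total",
            "long_indel_fraction",
            "short_error_total",
            "chimera_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.relative_particle_abundances is not None:
            ab = self.relative_particle_abundances
            if any(a < 0 for a in ab):
                raise ValueError("abundances must be non-negative")
            if abs(sum(ab) - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")
        if self.shear_mean <= 0 or self.pcr_bias_scale <= 0:
            raise ValueError("length parameters must be positive")
        if self.short_read_length < 1 or self.min_fragment < 1:
            raise ValueError("length parameters must be positive")


@dataclass
class IslandTruth:
    """One planted island: coordinates plus the cassette label per strain."""

    start: int
    end: int
    labels: list[str]               # per-strain label, index-aligned to strains
    cassettes: dict[str, str]       # label -> cassette sequence


@dataclass
class StrainSet:
    """A parent genome and its microdiverse strain cloud."""

    parent: ContigRecord
    strains: list[ContigRecord]
    target_pi: float
    island_truth: list[IslandTruth] = field(default_factory=list)


@dataclass
class SegmentTruth:
    """One error-free origin interval of a read, in parent-genome coordinates."""

    genome_id: str
    strain_id: str
    start: int
    end: int
    strand: str


@dataclass
class ReadTruth:
    read_id: str
    is_chimeric: bool
    segments: list[SegmentTruth]


@dataclass
class SimTruth:
    reads: dict[str, ReadTruth]
    genome_share: dict[str, float]  # expected read share (mass-weighted)
    islands: dict[str, list[tuple[int, int]]]  # genome -> planted coordinates


# ---------------------------------------------------------------------------
# genome and strain-cloud generation
# ---------------------------------------------------------------------------

def generate_genome(
    length: int,
    gc: float = 0.45,
    seed: int | np.random.Generator = 0,
    id: str = "genome",
    circular: bool = False,
) -> ContigRecord:
    """Random i.i.d. genome with the stated GC content."""
    if length < 1_000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0,1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.uint8)
    return ContigRecord(id, _decode(arr), circular=circular)


_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def generate_coding_genome(
    n_genes: int = 50,
    mean_gene_aa: int = 200,
    seed: int | np.random.Generator = 0,
    id: str = "coding_genome",
    circular: bool = False,
) -> ContigRecord:
    """Gene-dense genome: back-to-back ATG...stop genes of ~mean_gene_aa codons.

    Phage genomes are coding-dense, so frameshift-sensitivity analyses use
    this generator rather than uniform random sequence (whose open reading
    frames are short regardless of errors).
    """
    if n_genes < 1 or mean_gene_aa < 10:
        raise ValueError("need n_genes >= 1 and mean_gene_aa >= 10")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    parts: list[str] = []
    for _ in range(n_genes):
        n_aa = max(10, int(rng.normal(mean_gene_aa, mean_gene_aa * 0.2)))
        codons = rng.integers(0, len(_SENSE_CODONS), size=n_aa)
        gene = "ATG" + "".join(_SENSE_CODONS[c] for c in codons) + "TAA"
        parts.append(gene)
    return ContigRecord(id, "".join(parts), circular=circular)


def mutation_rate_for_pi(target_pi: float) -> float:
    """Per-site, per-strain mutation probability m giving expected pairwise
    diversity ``2m(1-m) + (2/3)m^2 = target_pi`` under independent mutation
    with a uniform alternate base."""
    if not 0.0 <= target_pi <= PI_SATURATION:
        raise ValueError(f"target_pi={target_pi} outside [0, {PI_SATURATION}]")
    if target_pi == 0.0:
        return 0.0
    # (4/3) m^2 - 2 m + pi = 0, smaller root
    disc = 4.0 - (16.0 / 3.0) * target_pi
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def make_strain_cloud(
    parent: ContigRecord,
    target_pi: float,
    n_strains: int,
    island_specs: list[tuple[int, int, int, float]] | None = None,
    seed: int | np.random.Generator = 0,
) -> StrainSet:
    """Build a microdiverse strain cloud around ``parent``.

    Outside islands, each site of each strain is independently mutated with
    the probability that calibrates the expected pairwise per-site diversity
    to ``target_pi``. Each island spec is ``(start, end, n_variants,
    presence_fraction)``: a strain keeps the parent cassette with probability
    ``presence_fraction``, otherwise it carries one of ``n_variants``
    unrelated random cassettes (uniformly chosen, shared across strains).
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    island_specs = sorted(island_specs or [])
    L = len(parent)
    prev_end = 0
    for start, end, n_var, pres in island_specs:
        if not (0 <= start < end <= L):
            raise ValueError(f"island [{start},{end}) outside parent bounds")
        if start < prev_end:
            raise ValueError("island specs overlap")
        if n_var < 1 or not 0.0 <= pres <= 1.0:
            raise ValueError("bad island spec")
        prev_end = end
    m = mutation_rate_for_pi(target_pi)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    parent_arr = _encode(parent.seq)

    island_mask = np.zeros(L, dtype=bool)
    for start, end, _, _ in island_specs:
        island_mask[start:end] = True

    # unrelated cassettes, one set per island, shared by all strains
    island_truths: list[IslandTruth] = []
    for start, end, n_var, _ in island_specs:
        cassettes = {"parent": parent.seq[start:end]}
        for v in range(n_var):
            arr = rng.choice(4, size=end - start).astype(np.uint8)
            cassettes[f"variant_{v}"] = _decode(arr)
        island_truths.append(IslandTruth(start, end, [], cassettes))

    strains: list[ContigRecord] = []
    for s in range(n_strains):
        arr = parent_arr.copy()
        if m > 0:
            mut = (rng.random(L) < m) & ~island_mask
            idx = np.nonzero(mut)[0]
            arr[idx] = (arr[idx] + rng.integers(1, 4, idx.size).astype(np.uint8)) % 4
        for it, (start, end, n_var, pres) in zip(island_truths, island_specs):
            if rng.random() < pres:
                label = "parent"
            else:
                label = f"variant_{rng.integers(0, n_var)}"
            it.labels.append(label)
            arr[start:end] = _encode(it.cassettes[label])
        strains.append(
            ContigRecord(f"{parent.id}|s{s}", _decode(arr), circular=parent.circular)
        )
    return StrainSet(parent, strains, target_pi, island_truths)


def make_community(
    params: SimParams,
    target_pi: float = 0.0,
    n_strains: int = 1,
    island_specs: list[tuple[int, int, int, float]] | None = None,
    seed: int | None = None,
) -> list[StrainSet]:
    """Convenience builder: ``n_genomes`` parents with lengths evenly spaced
    over the configured range, each wrapped in a strain cloud (or a
    single-strain set when ``n_strains == 1``)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.genome_length_range
    lengths = np.linspace(lo, hi, params.n_genomes).round().astype(int)
    sets = []
    for i, length in enumerate(lengths):
        parent = generate_genome(int(length), params.gc, rng, id=f"g{i}")
        if n_strains <= 1:
            sets.append(StrainSet(parent, [ContigRecord(f"{parent.id}|s0", parent.seq)], 0.0, []))
        else:
            sets.append(
                make_strain_cloud(parent, target_pi, n_strains, island_specs, rng)
            )
    return sets


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _mass_weights(strainsets: list[StrainSet], params: SimParams) -> np.ndarray:
    n = len(strainsets)
    ab = params.relative_particle_abundances
    if ab is None:
        ab = tuple(1.0 / n for _ in range(n))
    if len(ab) != n:
        raise ValueError("abundance vector length != number of genomes")
    w = np.array([a * len(ss.parent) for a, ss in zip(ab, strainsets)], dtype=float)
    return w / w.sum()


def _draw_fragment_length(rng: np.random.Generator, params: SimParams, gmax: int) -> int:
    """Lognormal shear length thinned by the PCR short-fragment preference
    exp(-L/pcr_bias_scale) (rejection sampling)."""
    mu = math.log(params.shear_mean) - params.shear_sigma**2 / 2
    lam = params.pcr_bias_scale
    for _ in range(10_000):
        L = rng.lognormal(mu, params.shear_sigma)
        if L < params.min_fragment or L > gmax:
            continue
        if rng.random() < math.exp(-(L - params.min_fragment) / lam):
            return int(round(L))
    return min(int(params.shear_mean), gmax)  # pathological parameters


def _apply_long_errors(
    arr: np.ndarray, p_err: float, indel_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, int, int, int]:
    """Apply substitution/insertion/deletion errors; return (seq, subs, ins, dels)."""
    L = arr.size
    if p_err <= 0.0:
        return arr.copy(), 0, 0, 0
    idx = np.nonzero(rng.random(L) < p_err)[0]
    if idx.size == 0:
        return arr.copy(), 0, 0, 0
    k = idx.size
    is_indel = rng.random(k) < indel_frac
    is_ins = is_indel & (rng.random(k) < 0.5)
    is_del = is_indel & ~is_ins
    is_sub = ~is_indel
    out = arr.copy()
    sub_idx = idx[is_sub]
    out[sub_idx] = (out[sub_idx] + rng.integers(1, 4, sub_idx.size).astype(np.uint8)) % 4
    rep = np.ones(L, dtype=np.int64)
    rep[idx[is_del]] = 0
    ins_idx = idx[is_ins]
    rep[ins_idx] = 2  # original base followed by an inserted base
    res = np.repeat(out, rep)
    if ins_idx.size:
        ends = np.cumsum(rep)
        res[ends[ins_idx] - 1] = rng.integers(0, 4, ins_idx.size).astype(np.uint8)
    return res, int(is_sub.sum()), int(is_ins.sum()), int(is_del.sum())


def _fragment_pieces(start: int, length: int, G: int, circular: bool) -> list[tuple[int, int]]:
    """Origin interval(s) of a fragment; circular genomes may wrap the origin."""
    if start + length <= G:
        return [(start, start + length)]
    if not circular:
        raise AssertionError("non-circular fragment out of bounds")
    return [(start, G), (0, start + length - G)]


def _simulate_one_fragment(
    strainsets: list[StrainSet],
    weights: np.ndarray,
    strain_arrays: list[list[np.ndarray]],
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[str, str, int, int, str]], list[tuple[int, int, int, int]]]:
    """Simulate one LASL fragment read segment.

    Returns (read_seq_piece, segments, counts) where segments are
    (genome_id, strain_id, ref_start, ref_end, strand) in read order and
    counts are per-segment (matches, mismatches, insertions, deletions).
    """
    gi = int(rng.choice(len(strainsets), p=weights))
    ss = strainsets[gi]
    si = int(rng.integers(0, len(ss.strains)))
    G = len(ss.parent)
    L = _draw_fragment_length(rng, params, G)
    if ss.parent.circular:
        start = int(rng.integers(0, G))
    else:
        start = int(rng.integers(0, G - L + 1))
    pieces = _fragment_pieces(start, L, G, ss.parent.circular)
    strand = "+" if rng.random() < 0.5 else "-"

    arrs, counts, read_lens = [], [], []
    for s, e in pieces:
        sub = strain_arrays[gi][si][s:e]
        errd, n_sub, n_ins, n_del = _apply_long_errors(
            sub, params.long_error_total, params.long_indel_fraction, rng
        )
        arrs.append(errd)
        span = e - s
        counts.append((span - n_sub - n_del, n_sub, n_ins, n_del))
        read_lens.append(errd.size)

    seq = _decode(np.concatenate(arrs)) if len(arrs) > 1 else _decode(arrs[0])
    if strand == "-":
        seq = revcomp(seq)
        pieces = pieces[::-1]
        counts = counts[::-1]
        read_lens = read_lens[::-1]
    genome_id = ss.parent.id
    strain_id = ss.strains[si].id
    segments = [(genome_id, strain_id, s, e, strand) for s, e in pieces]
    # attach read-space lengths so caller can assign read coordinates
    seg_counts = [
        (m, mm, ins, dl) for (m, mm, ins, dl) in counts
    ]
    return seq, segments, [(*c, rl) for c, rl in zip(seg_counts, read_lens)]  # type: ignore[misc]


def simulate_long_reads(
    strainsets: StrainSet | list[StrainSet],
    n_reads: int,
    params: SimParams,
    seed: int | None = None,
    id_prefix: str = "lr",
) -> tuple[list[ReadRecord], SimTruth, list[AlignmentRecord]]:
    """Simulate LASL long reads with indel-rich errors and chimeras.

    Truth alignments are expressed in parent-genome coordinates (strains are
    coordinate-identical to their parent) with edit counts measured against
    the origin *strain*, i.e. they describe sequencing error only, not strain
    divergence. Use :func:`parent_frame_alignments` for recruitment-style
    alignments that also account for strain-vs-parent divergence and island
    cassettes.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if isinstance(strainsets, StrainSet):
        strainsets = [strainsets]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    weights = _mass_weights(strainsets, params)
    strain_arrays = [[_encode(s.seq) for s in ss.strains] for ss in strainsets]

    reads: list[ReadRecord] = []
    truths: dict[str, ReadTruth] = {}
    alignments: list[AlignmentRecord] = []
    width = max(6, len(str(n_reads)))
    for i in range(n_reads):
        read_id = f"{id_prefix}{i:0{width}d}"
        chimeric = rng.random() < params.chimera_rate
        n_frag = 2 if chimeric else 1
        seq_parts: list[str] = []
        segs: list[SegmentTruth] = []
        offset = 0
        for _ in range(n_frag):
            seq, segments, counts = _simulate_one_fragment(
                strainsets, weights, strain_arrays, params, rng
            )
            seq_parts.append(seq)
            pos = 0
            for (g, s, rs, re_, strand), (m, mm, ins, dl, rlen) in zip(segments, counts):
                segs.append(SegmentTruth(g, s, rs, re_, strand))
                alignments.append(
                    AlignmentRecord(
                        read_id=read_id,
                        ref_id=g,
                        ref_start=rs,
                        ref_end=re_,
                        read_start=offset + pos,
                        read_end=offset + pos + rlen,
                        strand=strand,
                        matches=m,
                        mismatches=mm,
                        insertions=ins,
                        deletions=dl,
                        is_primary=(offset + pos == 0),
                    )
                )
                pos += rlen
            offset += len(seq)
        full = "".join(seq_parts)
        reads.append(ReadRecord(read_id, full, LONG_QUAL_CHAR * len(full)))
        truths[read_id] = ReadTruth(read_id, chimeric, segs)

    truth = SimTruth(
        reads=truths,
        genome_share={ss.parent.id: float(w) for ss, w in zip(strainsets, weights)},
        islands={
            ss.parent.id: [(it.start, it.end) for it in ss.island_truth]
            for ss in strainsets
        },
    )
    return reads, truth, alignments


def simulate_short_reads(
    strainsets: StrainSet | list[StrainSet],
    n_pairs: int,
    params: SimParams,
    seed: int | None = None,
    id_prefix: str = "sr",
) -> tuple[list[ReadRecord], SimTruth, list[AlignmentRecord]]:
    """Simulate 2 x short_read_length paired reads with substitution errors.

    Mates may overlap when the insert is shorter than twice the read length.
    R1 is forward on the genome, R2 reverse; mass-weighted genome sampling as
    for long reads.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if isinstance(strainsets, StrainSet):
        strainsets = [strainsets]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    weights = _mass_weights(strainsets, params)
    strain_arrays = [[_encode(s.seq) for s in ss.strains] for ss in strainsets]
    rl = params.short_read_length

    reads: list[ReadRecord] = []
    truths: dict[str, ReadTruth] = {}
    alignments: list[AlignmentRecord] = []
    width = max(6, len(str(n_pairs)))
    for i in range(n_pairs):
        gi = int(rng.choice(len(strainsets), p=weights))
        ss = strainsets[gi]
        si = int(rng.integers(0, len(ss.strains)))
        G = len(ss.parent)
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(rl, min(insert, G))
        start = int(rng.integers(0, G - insert + 1))
        frag = strain_arrays[gi][si][start : start + insert]
        for mate in (1, 2):
            read_id = f"{id_prefix}{i:0{width}d}/{mate}"
            if mate == 1:
                sub = frag[:rl].copy()
                rs, re_ = start, start + sub.size
                strand = "+"
            else:
                sub = frag[insert - rl :].copy()
                rs, re_ = start + insert - sub.size, start + insert
                strand = "-"
            n_err = 0
            if params.short_error_total > 0:
                idx = np.nonzero(rng.random(sub.size) < params.short_error_total)[0]
                n_err = idx.size
                sub[idx] = (sub[idx] + rng.integers(1, 4, idx.size).astype(np.uint8)) % 4
            seq = _decode(sub)
            if strand == "-":
                seq = revcomp(seq)
            reads.append(ReadRecord(read_id, seq, SHORT_QUAL_CHAR * len(seq)))
            truths[read_id] = ReadTruth(
                read_id,
                False,
                [SegmentTruth(ss.parent.id, ss.strains[si].id, rs, re_, strand)],
            )
            alignments.append(
                AlignmentRecord(
                    read_id=read_id,
                    ref_id=ss.parent.id,
                    ref_start=rs,
                    ref_end=re_,
                    read_start=0,
                    read_end=len(seq),
                    strand=strand,
                    matches=(re_ - rs) - n_err,
                    mismatches=n_err,
                )
            )
    truth = SimTruth(
        reads=truths,
        genome_share={ss.parent.id: float(w) for ss, w in zip(strainsets, weights)},
        islands={
            ss.parent.id: [(it.start, it.end) for it in ss.island_truth]
            for ss in strainsets
        },
    )
    return reads, truth, alignments


# ---------------------------------------------------------------------------
# parent-frame (recruitment-style) alignments
# ---------------------------------------------------------------------------

def parent_frame_alignments(
    strainsets: StrainSet | list[StrainSet],
    truth: SimTruth,
    truth_alignments: list[AlignmentRecord],
) -> list[AlignmentRecord]:
    """Re-express truth alignments against the parent genome, the way a read
    mapper recruiting reads back to a representative contig would see them.

    Strain-vs-parent point divergence is folded into the mismatch count, and
    alignment blocks are split around planted islands where the origin strain
    carries a non-parent cassette (those stretches are unalignable, as the
    cassettes are unrelated sequence). Sequencing-error counts are apportioned
    to blocks proportionally to block length. Segments falling entirely inside
    a foreign cassette yield no alignment.
    """
    if isinstance(strainsets, StrainSet):
        strainsets = [strainsets]
    by_genome = {ss.parent.id: ss for ss in strainsets}
    # cumulative strain-vs-parent mismatch counts, islands excluded
    diff_cum: dict[str, np.ndarray] = {}
    strain_islands: dict[str, list[tuple[int, int]]] = {}
    for ss in strainsets:
        parent_arr = _encode(ss.parent.seq)
        for k, strain in enumerate(ss.strains):
            diffs = (_encode(strain.seq) != parent_arr).astype(np.int64)
            foreign = []
            for it in ss.island_truth:
                if it.labels and it.labels[k] != "parent":
                    diffs[it.start : it.end] = 0  # handled by block splitting
                    foreign.append((it.start, it.end))
            diff_cum[strain.id] = np.concatenate(([0], np.cumsum(diffs)))
            strain_islands[strain.id] = foreign

    out: list[AlignmentRecord] = []
    for aln in truth_alignments:
        if aln.ref_id not in by_genome:
            continue
        cum = diff_cum.get(aln.read_id)  # noqa: F841 (strain lookup below)
        rt = truth.reads[aln.read_id]
        # find the strain for this segment
        seg = next(
            s
            for s in rt.segments
            if s.genome_id == aln.ref_id
            and s.start == aln.ref_start
            and s.end == aln.ref_end
        )
        strain_id = seg.strain_id
        cum = diff_cum[strain_id]
        # split the reference interval around foreign cassettes
        blocks: list[tuple[int, int]] = []
        pos = aln.ref_start
        for fs, fe in strain_islands[strain_id]:
            if fe <= aln.ref_start or fs >= aln.ref_end:
                continue
            if pos < fs:
                blocks.append((pos, min(fs, aln.ref_end)))
            pos = max(pos, fe)
        if pos < aln.ref_end:
            blocks.append((pos, aln.ref_end))
        span = aln.ref_span
        read_pos = aln.read_start
        for bs, be in blocks:
            blen = be - bs
            frac = blen / span
            mm_err = int(round(aln.mismatches * frac))
            ins = int(round(aln.insertions * frac))
            dl = int(round(aln.deletions * frac))
            dl = min(dl, blen - 1) if blen > 1 else 0
            strain_mm = int(cum[be] - cum[bs])
            mism = min(mm_err + strain_mm, blen - dl)
            matches = blen - dl - mism
            rlen = blen - dl + ins
            out.append(
                AlignmentRecord(
                    read_id=aln.read_id,
                    ref_id=aln.ref_id,
                    ref_start=bs,
                    ref_end=be,
                    read_start=read_pos,
                    read_end=read_pos + rlen,
                    strand=aln.strand,
                    matches=matches,
                    mismatches=mism,
                    insertions=ins,
                    deletions=dl,
                    is_primary=aln.is_primary,
                )
            )
            read_pos += rlen
    return out


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_manifest(params: SimParams, path: str | Path) -> None:
    """Persist all simulation parameters (including seed) as key=value lines."""
    with open(path, "w") as fh:
        for key, value in vars(params).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}={value}\n")


def read_manifest(path: str | Path) -> SimParams:
    kwargs: dict = {}
    defaults = SimParams()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        if not hasattr(defaults, key):
            raise ValueError(f"unknown manifest key {key!r}")
        current = getattr(defaults, key)
        if raw == "None":
            kwargs[key] = None
        elif isinstance(current, bool):
            kwargs[key] = raw == "True"
        elif isinstance(current, int):
            kwargs[key] = int(raw)
        elif isinstance(current, float):
            kwargs[key] = float(raw)
        elif isinstance(current, tuple) or current is None:
            parts = raw.split(",")
            vals = tuple(float(p) if "." in p else int(p) for p in parts)
            kwargs[key] = vals
        else:
            kwargs[key] = raw
    return replace(defaults, **kwargs)
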