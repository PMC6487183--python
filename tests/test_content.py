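import numpy as np
import pytest

import virionkit as vk
from virionkit.content import (
    arrangement_report,
    call_orfs,
    classify_spanning_reads,
    consensus_loci,
    project_interval,
)
from virionkit.datamodel import revcomp

ISLAND = vk.GenomicIsland("c1", 5_000, 8_000, 0.95, 1.0, 20.0)


def _aln(read_id, start, end, ref="c1"):
    n = end - start
    return vk.AlignmentRecord(read_id, ref, start, end, 0, n, "+", n, 0)


# ---------------------------------------------------------------------------
# spanning-read classification
# ---------------------------------------------------------------------------

def test_exact_border_coverage_is_full_span():
    res = classify_spanning_reads([_aln("r", 4_900, 8_100)], ISLAND)
    assert res.full_span_reads == ["r"]
    assert res.anchored_reads == []


def test_short_extension_excluded():
    res = classify_spanning_reads([_aln("r", 4_850, 5_500)], ISLAND)
    assert res.full_span_reads == [] and res.anchored_reads == []


def test_long_extension_anchored():
    left = classify_spanning_reads([_aln("r", 4_850, 6_200)], ISLAND)
    right = classify_spanning_reads([_aln("r", 6_800, 8_200)], ISLAND)
    assert left.anchored_reads == ["r"]
    assert right.anchored_reads == ["r"]


def test_full_span_takes_precedence():
    res = classify_spanning_reads(
        [_aln("a", 4_800, 8_200), _aln("b", 4_800, 6_500)], ISLAND
    )
    assert res.full_span_reads == ["a"] and res.anchored_reads == ["b"]


def test_island_at_contig_end_truncates_flank(caplog):
    isl = vk.GenomicIsland("c1", 50, 1_000, 0.95, 1.0, 20.0)
    with caplog.at_level("WARNING"):
        res = classify_spanning_reads(
            [_aln("r", 0, 1_150)], isl, contig_length=1_200
        )
    assert res.full_span_reads == ["r"]
    assert "truncated" in caplog.text


@pytest.mark.parametrize("seed", range(5))
def test_classification_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    alns = []
    for i in range(200):
        s = int(rng.integers(0, 11_000))
        e = s + int(rng.integers(200, 6_000))
        alns.append(_aln(f"r{i}", s, min(e, 12_000)))
    res = classify_spanning_reads(alns, ISLAND, border=100, min_ext=1000)
    full, anchored = [], []
    for a in alns:  # brute-force interval arithmetic
        s, e = a.ref_start, a.ref_end
        if s <= 4_900 and e >= 8_100:
            full.append(a.read_id)
        elif (s <= 4_900 and e >= 6_000) or (e >= 8_100 and s <= 7_000):
            anchored.append(a.read_id)
    assert sorted(res.full_span_reads) == sorted(full)
    assert sorted(res.anchored_reads) == sorted(anchored)


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

_SENSE = "GCT"  # alanine codon, no stop potential at this spacing


def test_single_long_orf():
    seq = "ATG" + _SENSE * 89 + "TAA"
    (orf,) = call_orfs(seq, min_aa=30)
    assert (orf.start, orf.end, orf.strand) == (0, len(seq), "+")
    assert orf.aa_length == 90
    assert (orf.end - orf.start) % 3 == 0


def test_no_start_codon_no_orfs():
    assert call_orfs("GCT" * 100, min_aa=1) == []


def test_longest_per_stop():
    # two ATGs share one stop; the first (longest ORF) is reported
    seq = "ATG" + _SENSE * 10 + "ATG" + _SENSE * 30 + "TAG"
    (orf,) = call_orfs(seq, min_aa=30)
    assert orf.start == 0 and orf.aa_length == 42


def test_strand_symmetry():
    rng = np.random.default_rng(80)
    g = vk.generate_coding_genome(n_genes=5, mean_gene_aa=80, seed=int(rng.integers(1e6)))
    fwd = call_orfs(g.seq, min_aa=30)
    rev = call_orfs(revcomp(g.seq), min_aa=30)
    L = len(g.seq)
    mirrored = sorted(
        (L - o.end, L - o.start, "-" if o.strand == "+" else "+", o.aa_length)
        for o in rev
    )
    assert mirrored == sorted((o.start, o.end, o.strand, o.aa_length) for o in fwd)


def test_frameshift_shortens_orfs():
    # an insertion inside a single isolated ORF strictly shortens the calls
    seq = "ATG" + _SENSE * 200 + "TAA"
    (orf,) = call_orfs(seq, min_aa=30)
    broken = seq[:300] + "A" + seq[300:]
    calls = call_orfs(broken, min_aa=1)
    assert max((c.aa_length for c in calls), default=0) < orf.aa_length


def test_orf_median_degrades_with_indel_rate():
    g = vk.generate_coding_genome(n_genes=40, mean_gene_aa=150, seed=82)
    ss = vk.StrainSet(g, [vk.ContigRecord(g.id + "|s0", g.seq)], 0.0, [])
    medians = []
    for rate in (0.0, 0.01, 0.05):
        params = vk.SimParams(
            n_genomes=1, long_error_total=rate, long_indel_fraction=1.0,
            chimera_rate=0.0, seed=0,
        )
        reads, _, _ = vk.simulate_long_reads(ss, 60, params, seed=83)
        aa = [o.aa_length for r in reads for o in call_orfs(r.seq, min_aa=30)]
        medians.append(np.median(aa))
    assert medians[0] > medians[1] > medians[2]


# ---------------------------------------------------------------------------
# projection and consensus loci
# ---------------------------------------------------------------------------

def test_project_interval_forward_and_reverse():
    aln = vk.AlignmentRecord("r", "c", 1_000, 2_000, 0, 1_000, "+", 1_000, 0)
    assert project_interval(aln, 100, 300) == (1_100, 1_300)
    aln_rev = vk.AlignmentRecord("r", "c", 1_000, 2_000, 0, 1_000, "-", 1_000, 0)
    assert project_interval(aln_rev, 100, 300) == (1_700, 1_900)


def test_project_interval_scales_through_indels():
    # read span 500 maps to ref span 1000: linear interpolation
    aln = vk.AlignmentRecord("r", "c", 0, 1_000, 0, 500, "+", 450, 0, 0, 550)
    assert project_interval(aln, 250, 500) == (500, 1_000)


def test_consensus_loci_linkage_rule():
    one = consensus_loci({"r1": [(100, 400)], "r2": [(100, 400)]})
    assert len(one) == 1 and one[0].support == 2

    linked = consensus_loci({"r1": [(100, 400)], "r2": [(140, 440)]}, tol=50)
    assert len(linked) == 1
    assert (linked[0].start, linked[0].end) == (120, 420)

    split = consensus_loci({"r1": [(100, 400)], "r2": [(160, 460)]}, tol=50)
    assert len(split) == 2


def test_arrangement_report_rules():
    def report(read_orfs):
        spanning = vk.SpanningReadSet(ISLAND, sorted(read_orfs), [])
        loci = consensus_loci(read_orfs)
        return arrangement_report(ISLAND, spanning, loci)

    # all reads share one signature
    shared = {f"r{i}": [(5_100, 5_700), (6_100, 6_900)] for i in range(6)}
    rep = report(shared)
    assert rep.alternative_arrangement is False
    assert rep.n_distinct_arrangements == 1

    # two cassettes, five reads each
    mixed = {f"a{i}": [(5_100, 5_700)] for i in range(5)}
    mixed.update({f"b{i}": [(6_100, 6_900)] for i in range(5)})
    rep = report(mixed)
    assert rep.alternative_arrangement is True
    assert rep.n_distinct_arrangements == 2

    # singleton support does not count
    lop = {f"a{i}": [(5_100, 5_700)] for i in range(9)}
    lop["b0"] = [(6_100, 6_900)]
    assert report(lop).alternative_arrangement is False

    # fewer than two full-span reads: not assessable
    assert report({"only": [(5_100, 5_700)]}).alternative_arrangement is None


def test_planted_cassette_arrangements_detected():
    """Simulator-planted two-cassette island: full-span reads split into two
    arrangement signatures."""
    parent = vk.generate_coding_genome(n_genes=30, mean_gene_aa=120, seed=90, id="p")
    L = len(parent)
    isl_start, isl_end = L // 2, L // 2 + 2_000
    ss = vk.make_strain_cloud(
        parent, 0.0, 20, island_specs=[(isl_start, isl_end, 1, 0.5)], seed=91
    )
    params = vk.SimParams(n_genomes=1, long_error_total=0.0, chimera_rate=0.0, seed=0)
    reads, truth, alns = vk.simulate_long_reads(ss, 250, params, seed=92)
    island = vk.GenomicIsland("p", isl_start, isl_end, 0.95, 1.0, 20.0)
    # use strain-frame truth alignments: spanning classification is coordinate-based
    spanning = classify_spanning_reads(alns, island, contig_length=L)
    assert len(spanning.full_span_reads) >= 10
    seqs = {r.id: r.seq for r in reads}
    by_read = {}
    for a in alns:
        by_read.setdefault(a.read_id, []).append(a)
    orfs_by_read = {}
    for rid in spanning.full_span_reads:
        aln = max(by_read[rid], key=lambda a: a.ref_span)
        proj = []
        for orf in call_orfs(seqs[rid], min_aa=30):
            lo, hi = project_interval(aln, orf.start, orf.end)
            if hi > isl_start and lo < isl_end:
                proj.append((lo, hi))
        orfs_by_read[rid] = proj
    loci = consensus_loci(orfs_by_read, tol=50)
    rep = arrangement_report(island, spanning, loci)
    assert rep.alternative_arrangement is True
    assert rep.n_distinct_arrangements >= 2
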