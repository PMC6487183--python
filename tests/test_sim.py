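import dataclasses
import io as stdio
import math

import numpy as np
import pytest

import virionkit as vk
from conftest import pairwise_pi


def _binom_3sigma(n, p):
    return 3 * math.sqrt(n * p * (1 - p))


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def test_generate_genome_deterministic():
    a = vk.generate_genome(10_000, 0.5, seed=1)
    b = vk.generate_genome(10_000, 0.5, seed=1)
    assert a.seq == b.seq


def test_generate_genome_gc_content():
    g = vk.generate_genome(100_000, 0.3, seed=2)
    gc = (g.seq.count("G") + g.seq.count("C")) / len(g)
    assert abs(gc - 0.3) < 0.02


@pytest.mark.parametrize("length,gc", [(0, 0.5), (500, 0.5), (10_000, 0.0), (10_000, 1.5)])
def test_generate_genome_preconditions(length, gc):
    with pytest.raises(ValueError):
        vk.generate_genome(length, gc, seed=1)


# ---------------------------------------------------------------------------
# strain clouds
# ---------------------------------------------------------------------------

def test_zero_pi_strains_identical():
    parent = vk.generate_genome(5_000, 0.5, seed=3, id="p")
    ss = vk.make_strain_cloud(parent, 0.0, 5, seed=4)
    assert all(s.seq == parent.seq for s in ss.strains)


def test_pi_saturation_rejected():
    parent = vk.generate_genome(5_000, 0.5, seed=3, id="p")
    with pytest.raises(ValueError):
        vk.make_strain_cloud(parent, 0.8, 5, seed=4)


def test_cloud_realizes_target_pi(strain_cloud):
    assert pairwise_pi(strain_cloud.strains) == pytest.approx(0.01, abs=0.002)


def test_mutation_rate_closed_form():
    for pi in (0.001, 0.01, 0.1, 0.5, 0.75):
        m = vk.mutation_rate_for_pi(pi)
        assert 2 * m * (1 - m) + (2 / 3) * m * m == pytest.approx(pi, rel=1e-12)


def test_island_cassette_presence_binomial():
    parent = vk.generate_genome(10_000, 0.5, seed=5, id="p")
    ss = vk.make_strain_cloud(
        parent, 0.0, 100, island_specs=[(2_000, 3_000, 1, 0.5)], seed=6
    )
    labels = ss.island_truth[0].labels
    n_parent = labels.count("parent")
    assert abs(n_parent - 50) <= _binom_3sigma(100, 0.5)
    # the cassette actually lands in the strain sequence
    for strain, label in zip(ss.strains, labels):
        assert strain.seq[2_000:3_000] == ss.island_truth[0].cassettes[label]


def test_overlapping_islands_rejected():
    parent = vk.generate_genome(10_000, 0.5, seed=5, id="p")
    with pytest.raises(ValueError, match="overlap"):
        vk.make_strain_cloud(
            parent, 0.0, 5, island_specs=[(100, 500, 1, 0.5), (400, 900, 1, 0.5)], seed=1
        )


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def test_long_reads_byte_identical_under_seed(small_community, small_params):
    out = []
    for _ in range(2):
        reads, _, _ = vk.simulate_long_reads(small_community, 100, small_params, seed=9)
        buf = stdio.StringIO()
        for r in reads:
            buf.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
        out.append(buf.getvalue())
    assert out[0] == out[1]


def test_errorfree_reads_are_exact_substrings(small_community, small_params):
    from virionkit.datamodel import revcomp

    params = dataclasses.replace(
        small_params, long_error_total=0.0, chimera_rate=0.0
    )
    reads, truth, _ = vk.simulate_long_reads(small_community, 50, params, seed=10)
    strains = {s.id: s.seq for ss in small_community for s in ss.strains}
    for r in reads:
        seg = truth.reads[r.id].segments[0]
        origin = strains[seg.strain_id]
        assert r.seq in origin or revcomp(r.seq) in origin


def test_read_conservation_and_unique_ids(small_community, small_params):
    reads, truth, _ = vk.simulate_long_reads(small_community, 500, small_params, seed=12)
    assert len(reads) == 500
    assert len({r.id for r in reads}) == 500
    assert set(truth.reads) == {r.id for r in reads}


def test_chimera_count_binomial(small_community, small_params):
    reads, truth, _ = vk.simulate_long_reads(
        small_community, 10_000, small_params, seed=13
    )
    n_chim = sum(t.is_chimeric for t in truth.reads.values())
    expected = 10_000 * small_params.chimera_rate
    assert abs(n_chim - expected) <= _binom_3sigma(10_000, small_params.chimera_rate)
    for t in truth.reads.values():
        if t.is_chimeric:
            assert len(t.segments) >= 2


def test_emitted_median_length_below_shear_mean(small_community, small_params):
    reads, _, _ = vk.simulate_long_reads(small_community, 2_000, small_params, seed=14)
    med = np.median([len(r) for r in reads])
    # PCR bias pulls the median to roughly half of the 8 kbp shear target
    assert 3_000 < med < 5_500


def test_mass_weighted_read_share():
    pa = vk.generate_genome(40_000, 0.5, seed=20, id="A")
    pb = vk.generate_genome(20_000, 0.5, seed=21, id="B")
    sets = [
        vk.StrainSet(pa, [vk.ContigRecord("A|s0", pa.seq)], 0.0, []),
        vk.StrainSet(pb, [vk.ContigRecord("B|s0", pb.seq)], 0.0, []),
    ]
    params = vk.SimParams(n_genomes=2, relative_particle_abundances=(0.5, 0.5), seed=0)
    _, truth, _ = vk.simulate_long_reads(sets, 6_000, params, seed=22)
    n_a = sum(
        1 for t in truth.reads.values() if t.segments[0].genome_id == "A"
    )
    assert truth.genome_share["A"] == pytest.approx(2 / 3)
    assert abs(n_a - 4_000) <= _binom_3sigma(6_000, 2 / 3)


def test_error_rate_recovery(small_community, small_params):
    _, _, alns = vk.simulate_long_reads(small_community, 2_000, small_params, seed=23)
    errs = sum(a.mismatches + a.insertions + a.deletions for a in alns)
    cols = sum(a.matches + a.mismatches + a.insertions + a.deletions for a in alns)
    observed = errs / cols
    assert abs(observed - 0.08) <= 0.2 * 0.08


def test_circular_genome_reads_may_wrap():
    parent = vk.generate_genome(6_000, 0.5, seed=30, id="circ", circular=True)
    ss = vk.StrainSet(parent, [vk.ContigRecord("circ|s0", parent.seq, circular=True)], 0.0, [])
    params = vk.SimParams(
        n_genomes=1, long_error_total=0.0, chimera_rate=0.0, seed=0
    )
    _, truth, alns = vk.simulate_long_reads(ss, 300, params, seed=31)
    wrapped = [t for t in truth.reads.values() if len(t.segments) == 2]
    assert wrapped, "expected some origin-wrapping fragments"
    for t in wrapped:
        segs = sorted(t.segments, key=lambda s: s.start)
        assert segs[0].start == 0 and segs[1].end == 6_000
        assert not t.is_chimeric


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------

def test_short_reads_errorfree_exact(small_community, small_params):
    from virionkit.datamodel import revcomp

    params = dataclasses.replace(small_params, short_error_total=0.0)
    reads, truth, _ = vk.simulate_short_reads(small_community, 50, params, seed=40)
    strains = {s.id: s.seq for ss in small_community for s in ss.strains}
    assert len(reads) == 100  # pairs
    for r in reads:
        seg = truth.reads[r.id].segments[0]
        origin = strains[seg.strain_id]
        expect = origin[seg.start : seg.end]
        assert r.seq == (expect if seg.strand == "+" else revcomp(expect))
        assert len(r) == params.short_read_length


def test_short_read_pair_counts_binomial():
    pa = vk.generate_genome(30_000, 0.5, seed=41, id="A")
    pb = vk.generate_genome(30_000, 0.5, seed=42, id="B")
    sets = [
        vk.StrainSet(pa, [vk.ContigRecord("A|s0", pa.seq)], 0.0, []),
        vk.StrainSet(pb, [vk.ContigRecord("B|s0", pb.seq)], 0.0, []),
    ]
    params = vk.SimParams(n_genomes=2, relative_particle_abundances=(0.5, 0.5), seed=0)
    _, truth, _ = vk.simulate_short_reads(sets, 10_000, params, seed=43)
    n_a = sum(
        1
        for rid, t in truth.reads.items()
        if rid.endswith("/1") and t.segments[0].genome_id == "A"
    )
    assert abs(n_a - 5_000) <= _binom_3sigma(10_000, 0.5)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def test_manifest_roundtrip(tmp_path):
    params = vk.SimParams(n_genomes=3, chimera_rate=0.02, seed=99)
    path = tmp_path / "run.cfg"
    from virionkit.sim import read_manifest, write_manifest

    write_manifest(params, path)
    assert read_manifest(path) == params
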