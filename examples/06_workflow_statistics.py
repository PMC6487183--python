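"""Workflow evaluation statistics on a simulated mock community.

Recovers the injected chimera rate from read alignments, measures indel
density per 100 kbp, checks the long-vs-short quantitativeness (R^2 of
per-genome median coverage), applies the 40% breadth filter, and computes a
hypergeometric enrichment p-value and a bootstrapped median effect size.
"""
import numpy as np

import virionkit as vk

params = vk.SimParams(
    relative_particle_abundances=(0.30, 0.25, 0.18, 0.12, 0.09, 0.06), seed=4
)
community = vk.make_community(params)
long_reads, truth, long_alns = vk.simulate_long_reads(community, 10_000, params, seed=5)
_, _, short_alns = vk.simulate_short_reads(community, 10_000, params, seed=6)

rate, _ = vk.chimera_rate(
    long_alns,
    read_lengths={r.id: len(r) for r in long_reads},
    ref_lengths={ss.parent.id: len(ss.parent) for ss in community},
)
true_rate = sum(t.is_chimeric for t in truth.reads.values()) / len(truth.reads)
print(f"chimera rate: recovered {rate:.2%} vs truth {true_rate:.2%}")

ins, dels, per100k = vk.indel_metrics(long_alns)
print(f"read indels: {ins} insertions, {dels} deletions "
      f"({per100k:.0f} per 100 kbp of aligned reference)")

med_long, med_short = [], []
for ss in community:
    dl, _ = vk.pileup(long_alns, ss.parent)
    ds, _ = vk.pileup(short_alns, ss.parent)
    med_long.append(float(np.median(dl)))
    med_short.append(float(np.median(ds)))
r2 = vk.abundance_r2(med_long, med_short, log_scale=True)
print(f"long vs short per-genome median coverage: R^2 = {r2:.3f} "
      "(LASL amplification retains relative abundance)")

rows = [
    vk.AbundanceRow("well_covered", 500, 0.93, 500.0),
    vk.AbundanceRow("partial_match", 120, 0.31, 120.0),
]
filtered = vk.breadth_filter(rows, threshold=0.40)
print("breadth filter (<40% -> zero abundance):",
      {r.contig_id: r.abundance for r in filtered})

# enrichment of one assembly class among top-abundance contigs
p = vk.hypergeom_enrichment(N=20_545, K=366, n=1_598, k=81)
print(f"hypergeometric enrichment of long-read contigs among the most "
      f"abundant: p = {p:.2e}")

rng = np.random.default_rng(7)
short_like = rng.normal(157, 40, size=3_000)   # protein lengths, aa
raw_like = rng.normal(72, 25, size=3_000)
es = vk.bootstrap_median_diff(raw_like, short_like, n_boot=1000, subsample=1000, seed=8)
print(f"bootstrapped median protein-length difference (raw long reads - "
      f"short contigs): {es.median_difference:.0f} aa "
      f"[{es.ci_low:.0f}, {es.ci_high:.0f}] 95% CI")
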