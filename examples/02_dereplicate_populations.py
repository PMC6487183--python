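"""Cluster contigs into viral populations at 95% ANI over 80% length.

Builds a parent genome plus two near-identical strains (>=99% ANI) and one
diverged relative (~89% ANI, the tig404-vs-HTVC010P regime), computes pairwise
ANI from k-mer-anchored alignment blocks, and dereplicates: the close strains
collapse into one population while the diverged genome stays separate.
"""
from itertools import combinations

import virionkit as vk

parent = vk.generate_genome(30_000, 0.45, seed=10, id="popA_rep")
near = vk.make_strain_cloud(parent, 0.01, 2, seed=11).strains      # ~99.5% ANI
far = vk.make_strain_cloud(parent, 0.20, 2, seed=12).strains[0]    # ~89% ANI
far = vk.ContigRecord("distant_relative", far.seq[:24_000])

contigs = [parent, vk.ContigRecord("popA_strain", near[0].seq), far]
table = []
for a, b in combinations(contigs, 2):
    blocks = vk.find_alignment_blocks(a, b)
    est = vk.block_ani(blocks, len(a), len(b))
    table.append(est)
    print(f"{a.id} vs {b.id}: ANI {est.ani:.3f} over {est.aligned_fraction:.0%} of shorter")

clusters = vk.dereplicate(contigs, table, ani_min=0.95, cov_min=0.80)
print(f"\n{len(contigs)} contigs -> {len(clusters)} populations")
for cl in clusters:
    print(f"  representative {cl.representative_id}: members {cl.member_ids}")
print("(members within 95% ANI / 80% length collapse; the ~89% relative stays apart)")
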