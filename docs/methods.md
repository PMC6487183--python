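# Methods

This note documents the models and procedures implemented in `virionkit`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. Conventions first: all internal
coordinates are 0-based half-open (BED-native); reverse-strand alignments
keep read coordinates on the forward (emitted) read with a strand flag, as in
PAF; alignment identity is `matches / (matches + mismatches + insertions +
deletions)`, and ambiguous bases (N) count as mismatches — a conservative,
deterministic choice.

## The mock-community simulator

The simulator emulates the data-generating process of a linker-amplified
shotgun library (LASL) of a pooled viral community, sequenced long
(nanopore-like) and short (Illumina-like), with complete ground truth.

**Community and read sampling.** Default community: six genomes with lengths
evenly spaced over 38.5–129.4 kbp (phage-sized), i.i.d. composition at GC
0.45, pooled at equal particle counts. Because shearing and amplification act
on the pooled DNA mass, reads are sampled per genome with probability
proportional to *particle abundance × genome length* (mass weighting), not
particle abundance alone. Within a population, the origin strain is uniform.

**Fragment lengths.** Shear lengths are lognormal with mean `shear_mean`
(8,000 bp) and log-sd `shear_sigma` (0.55). PCR preferentially amplifies
shorter fragments; we model this as rejection sampling with acceptance weight
`exp(−L/λ)`, `λ = pcr_bias_scale` (2,500 bp). The pair (σ = 0.55, λ = 2,500)
was fixed by numerically integrating the thinned density so that the emitted
median is ≈ 4.1 kbp — about half the shear target, the regime observed in
real LASL nanopore libraries. λ is exposed as a parameter since the bias
strength is library-dependent. Fragments on circular genomes may wrap the
origin (their truth splits into two colinear segments).

**Errors.** Long reads: each base is independently an error site with
probability `long_error_total` (0.08); an error is an indel with probability
`long_indel_fraction` (0.6; insertions and deletions equiprobable), otherwise
a substitution to a uniform alternate base. Short reads: 2 × 300 bp pairs
from ~700 ± 60 bp inserts (mates may overlap), substitution-only errors at
0.005. Quality strings are constant (Q10 long, Q30 short); downstream
analyses do not read them. No homopolymer, signal-level, or GC-efficiency
modelling — error *rates* and indel dominance are reproduced, error *contexts*
are not, so tests validate estimator behaviour, not basecaller realism.

**Chimeras.** With probability `chimera_rate` (0.0095, the observed LASL
chimera fraction) a read is the end-to-end join of two independently drawn
fragments — the simplest model consistent with reads mapping to more than one
locus. No linker sequence is inserted.

**Strain clouds.** A population is a parent genome plus `n_strains` variants.
Outside islands, each site of each strain mutates independently with
probability m solving `2m(1−m) + (2/3)m² = π_target` (exact for independent
mutation with a uniform alternate base; two strains differ at a site when
exactly one mutated, or both did and picked different bases, probability 2/3).
π saturates at 0.75. The realized cloud is validated against a brute-force
pairwise-difference oracle.

**Planted islands.** An island spec `(start, end, n_variants,
presence_fraction)` gives each strain the parent cassette with probability
`presence_fraction`, otherwise one of `n_variants` unrelated random cassettes
(uniform, shared across strains). Cassettes keep the parent's island length,
so strain and parent coordinates coincide everywhere — a deliberate
simplification that makes truth alignments exact; content, not length,
variation is what island detection and spanning-read analyses measure here.

**Truth alignments.** `simulate_long_reads` emits alignments in parent
coordinates whose edit counts measure sequencing error against the origin
strain. `parent_frame_alignments` re-expresses them the way a mapper
recruiting reads to the representative contig would see them: strain-vs-parent
divergence folds into the mismatch count, and blocks split around islands
where the origin strain carries a foreign cassette (unrelated sequence is
unalignable, so those stretches recruit nothing). Sequencing-error counts are
apportioned to split blocks proportionally to length; island studies in the
test-suite use error-free reads, where this is exact.

## Dereplication

Greedy star clustering: contigs sorted by length descending (ties broken by
id for full determinism); each contig joins the first cluster whose
*representative* it matches at ANI ≥ 0.95 and aligned fraction ≥ 0.80, else
founds a new cluster. Membership is tested against representatives only,
which makes the result order-independent given the sort and matches
longest-representative semantics. The aligned fraction is measured on the
**shorter** contig (the standard viral-population convention; the threshold's
reference length is not otherwise pinned down). ANI comes from caller-supplied
alignment blocks — whole-genome alignment is external — with a small exact
k-mer-anchored, ungapped X-drop extender (`k = 21`) provided for test
fixtures only.

## Genomic islands

Reads are assigned whole to an identity class by overall alignment identity
(as a mapper's identity filter would), pileup depth is summarised in 200 bp
windows at 100 bp step, and windows with median depth below
`α × median(window depths)` are flagged and merged (overlapping/abutting);
islands shorter than `min_len` (one window, 200 bp) are dropped — below
window resolution an island is not measurable. The α = 0.2 contig-relative
rule is **this package's** detection rule: it is scale-free, robust to overall
depth, and exposed in configuration; it is one reasonable member of the
family of under-recruitment rules used in island scans. Depth is monotone
non-increasing in the identity cutoff, hence total island extent is monotone
non-decreasing — the qualitative behaviour island analyses report across
92/95/98% cutoffs.

The simulated detection regime in tests places the representative's island
cassette in ~5% of a 200-strain cloud. That mirrors the method's target case
— a long-read assembly captures one cassette haplotype among many circulating
variants, so the island recruits almost nothing — and keeps the expected
island depth (≈ 5% of the contig median) several standard deviations below
the 20% calling threshold; with small clouds or common cassettes the island
depth approaches the threshold and calls become noise-limited, which is a
property of the biology, not the detector.

## Nucleotide diversity

Per-site π uses the unbiased pairwise form `π = n/(n−1)(1 − Σ p_b²)`, exactly
the fraction of differing unordered read pairs at the column (asserted
against brute force). Deletion-spanning reads are excluded from n (π is
defined over substitutions); sites with n < `min_depth` (default 10, standard
practice — exposed in config) are absent, never zero, and a genome with no
qualifying site is explicitly "not computable". Group contrasts use the
two-sided Mann–Whitney U from scipy (exact for small tie-free samples, normal
approximation with tie correction otherwise); the fold difference is a ratio
of medians, undefined when the denominator median is zero. Base counts are
obtained by re-aligning each recruited read segment to its reference interval
with edlib (gapless segments are accumulated directly).

## Island content from spanning reads

Full-span reads cover `[start − border, end + border)` (border 100 bp);
anchored reads cover one flank by ≥ border and extend ≥ `min_ext` (1 kb,
capped at the island length) into the island; full-span takes precedence and
flanks truncate at contig ends with a warning. The ORF caller is a deliberate
stand-in for a gene predictor: six frames, ATG-only starts, longest ORF per
stop, ≥ 30 aa. All protein-length analyses are therefore *comparative* (same
caller on all inputs), never absolute. `aa_length = (end − start)/3 − 1`
counts residues including the initial Met and excluding the stop. Read ORFs
project to contig coordinates linearly between the alignment's endpoints
(robust to indels without per-base liftover). Consensus loci are
single-linkage clusters of (start, end) pairs linking when both boundary
differences are ≤ 50 bp (the clustering threshold is a free parameter of
boundary clustering; 50 bp tolerates indel-driven projection jitter and is
exposed in config); an island shows alternative arrangements when ≥ 2
distinct locus-presence vectors each have ≥ 2 supporting full-span reads.
Functional annotation of loci is out of scope; reports carry coordinates and
optional user labels.

## Evaluation statistics

*Chimeras*: a read is chimeric when any two of its alignments are
non-colinear — different references, a strand switch, or a same-strand gap
exceeding `max_gap_factor` (2.0) × read length; with known reference lengths
the gap is also evaluated across the circular origin so wrapped fragments are
not miscalled. *Indels*: `(Σins + Σdel) / Σ aligned reference bp × 10⁵`;
polishing deltas are differences of totals and additive over partitions.
*Bootstrap effect sizes*: 1000 bootstraps of 1000-with-replacement subsamples
per group (capped at sample size), difference of medians with orientation
fixed as A − B, 2.5/97.5 percentile interval. *Breadth filter*: strictly
less-than 0.40 zeroes abundance; the boundary value is retained. *Abundance*
is the raw best-alignment read count (ties to the first-seen reference);
expectation–maximisation apportionment of multi-mappers belongs to external
quantifiers and is not re-implemented. *Enrichment*: exact upper-tail
hypergeometric `P(X ≥ k)` via scipy, cross-checked in tests against integer
tail-sum enumeration for all N ≤ 60. *Quantitativeness*: squared Pearson
correlation of per-genome values, optionally on log10(x + 1).

## Problem sizes and numerical notes

The test-suite and the acceptance script run simulations at desk scale, the
package's own choice of statistically comfortable sizes: 50,000 reads for
chimera-rate recovery (binomial 3σ ≈ 0.13 percentage points), 100 kbp ×
50-strain clouds at ~80× depth for π recovery at targets 0.001–0.03 (site-
averaging keeps the realized-cloud noise below ±20% at the smallest target),
40 kbp × 200-strain clouds at ~80× for island recovery, 100 replicates ×
1000 bootstraps for CI calibration. Degenerate inputs are handled explicitly:
empty alignment sets give zero depth vectors; an all-zero coverage profile
flags the whole contig with a warning; contigs shorter than one window
collapse to a single whole-contig window; zero-variance vectors and
zero-denominator folds are errors or undefined, never silent zeros.

## Known limitations

Strains and parents share coordinates (no structural variation outside
cassette replacement, no island length polymorphism). The simulator's error
model is context-free. The block finder is fixture-grade (forward strand,
ungapped). Read ORF projection is endpoint-linear, so locus boundaries jitter
with indel density. Chimera classification sees only supplied alignments; a
chimera whose two fragments happen to be colinear on one genome is
undetectable in principle and counted as such.
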