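# Methods

This note documents the models, rules and numerical choices behind
glycochrom, what the synthetic-data generators do and do not emulate, and
the design decisions taken where more than one reading was defensible.

## Coordinate conventions and the overlap engine

All intervals are 0-based half-open (BED convention) internally; GTF input
(1-based inclusive) is converted on read by `start → start − 1`.  Two
intervals overlap iff they share ≥ `min_bp` bases, computed as
`min(e1, e2) − max(s1, s2)` on the same chromosome; strand is ignored for
overlap testing, entering the analysis only through the strand-aware TSS/TES
anchors from which windows are built.  `min_bp` defaults to 1, the most
permissive reading of "overlapping", and is a parameter everywhere.
Chromosome names are matched by exact string equality; when two interval
sets share no chromosome name a loud warning lists both name sets (the
classic `chr1` vs `1` failure mode) rather than silently returning nothing.

Set algebra (merge / intersect / subtract / union) is implemented as sorted
sweeps over per-chromosome coordinate arrays; outputs are always sorted and
non-overlapping.  The test suite verifies the algebra base-for-base against
a per-base boolean-bitmap oracle on toy chromosomes and against `bedtools`
as an independent implementation.  Merging collapses abutting intervals
(`[0,100) + [100,200) → [0,200)`), which matters only for interval counts,
never for covered bases.

Anchor windows are `[point − flank, point + flank + 1)` — length
`2·flank + 1`, symmetric around the anchor base — clipped at chromosome
bounds rather than rejected.  The promoter window default is
`flank = 1000` (TSS ± 1 kb).

## The seven compartments

Each compartment is a merged interval set built by one rule from mark/factor
peak sets and gene anchors:

| compartment | rule | retained interval |
|---|---|---|
| ActivePromoter | H3K27ac peaks overlapping a TSS ± 1 kb window | the peak |
| TranscriptionInitiation | TSS ± 1 kb windows overlapping a Ser5P peak | the window |
| Heterochromatin | H3K9me3 peaks | the peak, verbatim |
| BivalentPromoter | TSS windows overlapped by both H3K4me3 and H3K27me3 | the window |
| Polycomb | Suz12 ∩ RING1B | the base-pair intersection |
| TranscriptionElongation | Ser2P peaks overlapping TSS + 1 kb → TES | the peak |
| TranscriptionTermination | 50 bp immediately downstream of each TES | the window |

The "peak vs window" column follows the literal phrasing of each rule; a
`retain` switch per promoter-anchored rule flips the reading.  Polycomb uses
the base-pair intersection as the most conservative, merge-distance-free
definition of "peaks overlapping each other"; a reciprocal-union mode is
available.  The termination window is `[tes+1, tes+51)` on plus-strand genes
and `[tes−50, tes)` on minus-strand genes — termination sites lie downstream
of the 3′ end.  Genes of length ≤ 1 kb contribute no elongation body (the
1 kb offset would pass the TES).  Missing marks disable their compartment
with a warning instead of failing the whole map.

Classification is multi-membership: every query peak carries the set of
compartments it overlaps (possibly empty → "unassigned"); there is no
priority cascade.  Counts are reported both as exclusive label combinations
(the upset representation; they always sum to the query peak count) and as
marginal per-compartment totals, since published bar plots can be read
either way.  Query peaks are classified as given — no clipping to a
consensus chromosome set is applied.

## Promoter co-occupancy screen

The screen statistic is peak-level recall of the query: after restricting
query peaks to those overlapping a TSS ± 1 kb window, each reference set is
scored by `100 · k / n` where `k` is the number of promoter query peaks hit
by ≥ 1 reference peak.  Only the query is promoter-restricted; references
are used as-is.  Rows are ranked by descending percentage with lexicographic
id tie-breaks so output is deterministic.  An optional base-pair mode
reports the Jaccard index of covered bases instead.  Pairing two screens of
the same library yields `fold_change = percent_after / percent_before`;
a zero "before" percentage is reported as `undefined(0→x)`, never as a
silent infinity.  No enrichment p-value is attached by default — the
statistic is a raw percentage.

## RPGC coverage and signal matrices

Coverage is computed from fragment intervals.  Each fragment is optionally
extended to `extend_to` bp (default 150) from its 5′ end in strand
direction — unstranded fragments extend rightward — mimicking single-end
read extension; per-base depth is accumulated and averaged over fixed bins
(default 50 bp).  The RPGC scale factor is

    scale = effective_genome_size / (total covered fragment bases),

which equals the textbook `G / (N · L)` whenever no fragment is clipped at a
chromosome boundary, and — unlike `G / (N · L)` — keeps the 1× invariant
(`genome mean = 1 ± 1e−9`) exact under clipping.  Bin values are mean
per-base coverage (not sums), so constant tracks are invariant to bin size.
Tracks are serialised as 4-column bedGraph with equal-value runs collapsed.

`matrix_around_centers` extracts `2·flank/bin` bins (40 at ± 1 kb / 50 bp)
over `[center − flank, center + flank)` with `center = ⌊(start+end)/2⌋`;
bases outside the chromosome contribute 0.  `matrix_over_genes` uses the
scale-regions layout — `flank/bin` upstream bins, the gene body resampled to
`body_bins` segments with linearly spaced boundaries (mean per segment;
genes shorter than `body_bins` reuse the nearest base), `flank/bin`
downstream bins; 40 + 100 + 40 = 180 columns at defaults.  Minus-strand rows
are computed on the reversed per-base profile, so transcription runs left to
right in every row and the minus-strand profile of a mirror-symmetric locus
is exactly the reverse of the plus-strand one.  No per-row normalisation is
applied by default.

## Occupancy clustering

Rows (regions) are described by the concatenation of their per-condition
profiles (a `fit_on="first"` mode clusters on the first condition only) and
clustered with k-means (k-means++ seeding, Lloyd iterations, best of
`n_init = 10` restarts; default k = 5).  Clusters are renumbered 1..k by
descending mean signal so "cluster 1" is stable across seeds; results are
bit-reproducible for a fixed seed.  Each cluster is then categorised from
`Δ = log2((mean_after + ε) / (mean_before + ε))` with `ε = 1e−3`:
gain if `Δ ≥ τ`, loss if `Δ ≤ −τ`, else unchanged.  `τ = 0.5` (≈ 1.4-fold)
is a configuration value surfaced in every report, not a constant.

The distance is Euclidean on untransformed profiles by default, with an
optional `log1p` transform.  The pipeline configuration enables `log1p`:
region-to-region depth variation is multiplicative, so in log space it
becomes an additive offset shared by the before and after halves of the
profile, and cluster boundaries align with fold-change structure rather
than with raw amplitude.  On the planted three-class fixture (2× gain,
0.5× loss, unchanged; 100 regions per class; depth CV 0.2) this choice
recovers ≥ 95% of planted categories across seeds, where untransformed
profiles dip to ~92% on unfavourable seeds.

Note that RPGC rescales each condition to a 1× mean, so planted fold
changes appear compressed by the ratio of total signal between conditions
(with equal class counts, a planted 2× gain measures ≈ 1.7×); the
categorisation threshold τ = 0.5 comfortably brackets this.

## Occupancy–expression link

`stratify_by_occupancy` defines occupied promoters as genes whose TSS ± 1 kb
window overlaps ≥ 1 query peak ("any qualifying overlap"; an optional
top-n-by-peak-score mode approximates a "highly occupied" selection, with n
as configuration).  Matched control groups — an equal-size seeded simple
random sample of zero-overlap genes, and of all genes — are drawn uniformly
without replacement, with no expression matching.  The reported test is
occupied vs unoccupied, two-sided Mann–Whitney–Wilcoxon.

The test statistic is `min(U_x, U_y)` with `U_x` counting pairs
`x_i > y_j` plus half the ties.  The p-value is exact — by full null
enumeration — whenever `|x| + |y| ≤ 16` with no ties, and otherwise uses the
normal approximation with tie and continuity corrections.  The test suite
checks exactness against an independent full-enumeration oracle for every
rank pattern with `|x| + |y| ≤ 10`, verifies type-I calibration at α = 0.05
over 1000 null replicates, and power ≥ 99% at a +1 SD shift with n = 200
per group.

`call_direct_targets` takes an externally produced differential-expression
table (gene id, log2 fold change, adjusted p) — differential-expression
modelling itself is out of scope — keeps rows with adjusted p below α
(default 0.05), assigns direction from the sign of the fold change, and
flags genes whose promoter window overlaps ≥ 1 peak as direct targets.
A gene-body overlap mode is available as an alternative to the promoter
window.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a single master seed; per-generator
sub-streams are derived with fixed offsets so adding a generator never
perturbs existing outputs.

* **Genome and genes** — a toy multi-chromosome genome (default 2 × 4 Mb)
  with 300 non-overlapping genes of 3–8 kb, random strands and jittered
  spacing, confined to the first 60% of each chromosome so a gene-free zone
  remains for intergenic compartments and background peaks.  Gene gaps
  (6–12 kb) keep promoter windows of neighbouring genes disjoint, which is
  what makes exact label recovery a meaningful test.
* **Compartment marks** — for each planted compartment instance, the
  minimal mark constellation that fires exactly that rule (e.g. H3K4me3 and
  H3K27me3 peaks inside one TSS window for a bivalent promoter; mutually
  overlapping Suz12/RING1B intervals at gene-free loci for Polycomb), with
  instances spatially disjoint.  The default mix plants 160 instances
  across all seven compartments for 200 query peaks, the remainder being
  unassigned background — proportions chosen to echo the promoter- and
  heterochromatin-dominated distribution seen in real pan-O-GlcNAc
  profiles.
* **Reference libraries** — for each planted fraction f, `round(f·n)` of
  the n promoter query peaks are covered by construction, so recovered
  percentages are exact and rank correlation with the planted fractions
  is 1.
* **Occupancy fragments** — per region a depth factor is drawn once from a
  unit-mean log-normal with CV 0.2 (within-class depth variation) and the
  class fold change (gain 2×, loss 0.5×, unchanged 1×; 100 regions per
  class) is applied exactly to the after-condition count, so each region
  realises its planted fold change up to count rounding.  Fragments are
  150 bp, centred uniformly within ± 300 bp of the region center.
* **Expression** — log-normal baseline (σ = 1 in log space); occupied
  genes' log expression is shifted by `shift · σ` (default 1 SD).  A zero
  shift makes the groups exchangeable, which underpins the type-I
  calibration test.

What the generators deliberately do **not** model: read-level sequencing
error, GC and mappability bias, peak-caller noise, replicate structure,
overdispersion beyond the single log-normal depth factor, and correlated
occupancy between neighbouring promoters.  Passing the planted-truth tests
therefore demonstrates the correctness of the interval algebra, rules,
normalisation and statistics — not robustness to every artefact of real
sequencing data.

## Problem sizes and determinism

Default problem sizes (2 × 4 Mb genome, 300 genes, 200 query peaks, 300
occupancy regions, ~30k fragments per condition) were chosen so the full
pipeline runs in about a second and the complete test suite in well under a
minute, while keeping every planted structure large enough for the recovery
guarantees to be non-trivial.  All stochastic steps (simulation,
control-group sampling, k-means restarts) consume explicit seeds; the
end-to-end pipeline writes a `report.json` whose content is identical across
reruns with the same configuration, apart from the timestamp.

## Known limitations

* The compartment rules are fixed, literal re-implementations; no
  signal-driven chromatin-state learning (ChromHMM-style) is attempted.
* bigWig binary I/O is not implemented; bedGraph is the native track
  format.
* The co-occupancy screen scores peak-level recall only (plus the optional
  base-pair Jaccard); no permutation null is run by default.
* `overlaps()` uses a vectorised per-query scan that is quadratic in the
  worst case; it is ample for peak-scale inputs (10²–10⁵ intervals) but not
  tuned for base-resolution fragment sets, for which only the binned
  coverage path is intended.
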