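# Methods

## Coordinates and conventions

Genomic coordinates are 0-based half-open. All analyses run in transcript
space: offset 1 is the first nucleotide 3' of the stop codon's last base on
the sense strand, so minus-strand genes are handled once at load/assignment
time and every downstream statistic is strand-agnostic. A gene's analysis
window is `(upstream_extent, downstream_extent)` around the stop codon —
(0, 1500) for the yeast profile, (1000, 5000) for the human profile, and
(0, utr_len) for synthetic genes.

Species profiles bundle every analysis constant so yeast and human settings
cannot be mixed silently: cluster gap 4 nt; yeast major-isoform rule
count ≥ 5% of the gene's maximum isoform (a strict-> variant is a flag;
the two conventions differ only at exact boundaries); human rule
strictly >5% at high depth, or an absolute ≥5-read floor when the maximum
isoform holds <100 reads in either genotype; yeast gene floor 1000 reads
(human: none beyond requiring ≥2 common major isoforms — configurable);
library scale target 25,000,000; slope quality gates |R| > 0.7 (yeast) /
0.6 (human); GC-scan gate |R| > 0.5; within-cluster spacing bins 1–15
(yeast) / 1–14 (human); mapping truncation 17 / 77 nt.

## Read processing

A 3' READS read is 4 random nt, a T-run (the reverse complement of the
poly(A) tail; its length equals the number of 3'-terminal As of the
fragment), then the reverse complement of the sense strand ending at the
cleavage site. Preprocessing enforces the first-T rule (a non-T first base
means the fragment did not end in A), records the T count, and truncates the
remainder. Reads that are all Ts after the leader have no mappable remainder
and are dropped with a logged reason.

The internal-priming filter retains a mapped read iff the uninterrupted
sense-strand A-run starting immediately 3' of its mapped end is shorter than
its T count — i.e. at least one tail A must be non-templated. The run is
measured literally (uninterrupted As only) and scanning stops at the T count,
so the filter is O(t) per read.

Mapping itself is out of scope; a naive exact-match aligner (unique
full-length match of the trimmed read or its reverse complement, else drop)
is provided solely for fixture-scale end-to-end tests. Fragments overlapping
genomic A-runs can legitimately multi-map and are dropped, as a real aligner
would at MAPQ 0.

Overlapping gene windows assign an endpoint to the gene whose stop codon is
nearest upstream, logged as ambiguous. Mitochondrial contigs are excluded
under the human profile.

## Clusters and the permutation null

A cluster is a maximal run of major-isoform endpoints with consecutive
positional differences ≤ 4 (adjacent bases have difference 1). The per-gene
cluster pattern is the multiset of cluster sizes; pattern identity in the
null test means exact multiset equality.

The null re-places the gene's k major isoforms uniformly without replacement
over the non-A positions of its 3'UTR (genomically encoded terminal As are
indistinguishable from tail As, so A positions can never host a detected
endpoint), 100,000 times by default. p is the fraction of shuffles whose
pattern equals the observed one, floored at 1/n_shuffles when no shuffle
matches; results report −log10 p with the conventional significance line at
2. k-subsets are drawn vectorised (k smallest of m uniforms per row), ~1 s
per gene per 10^5 shuffles. An exact enumeration oracle
(`exact_pattern_probability`) covers genes with C(m, k) ≤ 10^6 and anchors
the Monte-Carlo tests. Genes with more isoforms than eligible positions
raise an error rather than degrade.

## Utilization, slopes, and spacing medians

Relative expression divides an isoform's scaled count by the gene's total
over the isoforms retained after combining genotypes (the common majors).
Any gene-constant denominator gives identical ratio-of-ratio and slope
statistics up to a per-gene constant; common-major normalisation makes u
comparable across genes. u(p) = rel_mut(p)/rel_wt(p).

Cluster slopes are ordinary least squares of u against offset for clusters
of ≥4 common majors, with the Pearson R of the same points as the quality
gate; constant-u clusters have undefined R and are flagged out of gated
analyses. Within-cluster spacing medians use *all* ordered pairs (not only
adjacent) inside gated clusters; between-cluster statistics use one boundary
pair per adjacent cluster pair (3'-most of the upstream cluster, 5'-most of
the downstream; distance is their positional difference), including small
clusters by default (a `min_cluster_size` flag excludes them — the ≥4 rule
applies only to slope fitting). The neighboring-pair analysis is
cluster-agnostic: adjacent common majors only.

Three pair statistics exist behind `stat_kind` — relative ratio
u_down/u_up, percent difference 100·(u_down−u_up)/u_up, and plain
difference — because figure-style summaries use the ratio while the
cluster-independent analysis uses the difference. Medians, never means, are
reported per spacing bin.

## GC elements

Window GC is the G+C fraction of a 10-nt sense-strand window; the scan
anchors downstream windows (+1..+100) at the cluster's 3'-most isoform and
upstream windows (−100..−1) at its 5'-most, computes Pearson R and two-sided
p between GC and slope across |R|>0.5 clusters at each start, and applies
Benjamini–Hochberg FDR at q<0.05 across the starts within a region (the
cutoff is a parameter; 0.05 is the default choice). A window "starting at
s" spans s..s+9 inclusive.

The quintile analysis sorts gated slopes ascending (stable on ties), splits
them into five near-equal groups, and reports each quintile's mean percent
change of GC at +13..+30 (relative to the 3'-most isoform) against a
background defined as the median GC over all 18-nt windows fully inside the
analysed genes' 3'UTRs — the most reproducible reading of "equivalent
genomic positions within 3'UTRs"; the background is an explicit parameter.

Note a statistical property of the scan on strongly coupled data: with ~25
true-positive windows among 91, the BH cutoff rises enough to admit an
occasional null window at ~2.4σ (|R| ≈ 2.4/√n_clusters), independent of
sample size. Expect a borderline out-of-band window in roughly a quarter of
simulated datasets; the element itself is unambiguous (R up to ~0.55 inside
+4..+30 window starts).

## Occupancy metagenes

Nascent reads collapse to the RNA 3'-end base (last base for +, first for −)
with MAPQ strictly >10, optional protein-coding-proximity (±5 kb) and
snoRNA-exclusion filters. Libraries are matched by multivariate
hypergeometric downsampling to the smallest total. Poly(A) anchors need ≥20
reads within ±100 nt and ≥1 read in the first 100 nt downstream in every
library; decoy anchors are sense-strand AATAAA matches in introns strictly
longer than 10 kb, re-centred so the hexamer occupies −25..−20 of a nominal
cleavage site (anchor = hexamer start + 25 in transcript direction), with
≥10 reads in ±100 nt and a non-zero downstream count per library.

Profiles cover offsets −100..+100 in transcript orientation. Signal is the
per-offset sum over anchors (a mean-per-site variant is a flag — the
plotted units of such figures are conventionally unstated); AT composition
is the per-offset percent of anchors with A or T, used for both anchor
classes (for a binary per-site indicator the per-position percent is the
reproducible statistic; a median variant exists behind the same flag).

## The synthetic-data generator

What it emulates: per-gene clustered poly(A) endpoints inside a 200-nt end
zone (one contig per gene; 150-nt coding pad, 220-nt downstream pad);
intra-cluster gaps 1–4 nt and inter-cluster gaps 35–60 nt; lognormal
(σ = 0.5) baseline isoform weights; a slow-mutant genotype whose usage
declines geometrically by r per nt within a cluster (default r = 0.9) and
by a constant 0.98 across each cluster boundary, carried over between
clusters so boundary pairs measure ≈0.98; per-cluster tilt heterogeneity
r_c = r^s with s ~ U(0.75, 1.25) (median cluster tilt is exactly r, so
pooled spacing medians remain comparable to r^d while slopes vary across
clusters); optional GC elements: with coupling γ the 18-nt window at
+13..+30 downstream of each cluster is rewritten at GC fraction
0.35 + γ(s−1)/0.5, making downstream GC increase with elongation-rate
sensitivity; 3' READS reads with non-templated tail length 1 + geometric
(mean 8, minimum 1 — at least one non-templated A is required and the
distribution is otherwise unconstrained) and internal-priming artifacts
ending at a planted 8-nt genomic A-run with tail length ≤ run length;
occupancy tracks with a 0.6× dip on −40..−1 and bumps of 1.5× on +10..+25
and 2.5× on +30..+100 per endpoint (Poisson counts; the slow mutant scales
the second bump by 1.2); and long-intron fixtures with planted AATAAA
hexamers plus flat Poisson coverage for decoy controls.

Two deliberate structural choices:

- Endpoints (and the base just 3' of each) are placed on non-A sense bases,
  with A→T substitution. Non-A placement mirrors the analysis-side
  A-exclusion so truth stays recoverable through the real filter; the next
  base being non-A ensures a genuine read is never eaten by the
  internal-priming rule; and T (rather than a random non-A base) keeps the
  substitution GC-neutral so forced bases cannot leak into GC statistics —
  AU-rich poly(A) context is also what real sites look like.
- The gene's single slope-analyzable cluster (4–8 isoforms) is 5'-most;
  downstream clusters hold 1–3 isoforms. Because the mutant/WT level carries
  over between clusters, a downstream cluster's u-slope scales with the
  decline accumulated upstream of it; anchoring the analyzable cluster at
  level 1 makes its slope reflect its own tilt, which is what the GC
  coupling and quintile analyses presuppose. Pair-ratio statistics are
  level-invariant and unaffected.

What it does not emulate: sequencing errors, splicing, annotation errors,
UMI duplication, mappability structure beyond exact matches, inter-gene
overlap, or realistic genome-scale gene counts. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to real-library artifacts beyond internal
priming.

Two simulation routes exist: full read-level FASTQ (exercises trimming,
alignment, filtering) and direct multinomial endpoint counts
(`simulate_endpoint_counts`) for transcriptome-scale analyses — both sample
the same truth weights.

## Numerical choices and degenerate inputs

Scaling preserves proportions exactly and is idempotent at the target;
all-zero inputs are an error. Empty isoform tables, windows off contigs,
more isoforms than eligible positions, and zero-variance correlations
raise or flag rather than return silent values; windows are skipped
per-position (and logged via exclusion counts) only where the operation
defines it. All randomness flows through `numpy.random.Generator` with
explicit seeds; identical seeds give identical outputs, including
byte-identical FASTA.

Problem sizes used by the test and acceptance runs: 200 genes at 10^5
reads/gene for shift and GC analyses (≈200 gated clusters, enough that
spacing medians sit within ±0.02 of r^d and quintile contrasts resolve);
50 small genes for Monte-Carlo/exact agreement at 10^5 shuffles; 5 genes at
10^6 occupancy reads for metagene recovery. Quintile monotonicity is
assessed on quintile means pooled over five simulation seeds: a single
dataset's per-quintile mean GC (18-nt windows, ~40 clusters per quintile)
carries ±5-point noise and can show 1–2-point adjacent inversions.

## Known limitations

- The naive aligner is exponential in nothing but is exact-match only; it
  exists for fixtures, not for real libraries.
- The human arm reuses the yeast machinery with profile constants; no
  human-specific GC analysis is provided (by design, the sliding-window GC
  analysis is a yeast-scale analysis).
- The permutation null treats major isoforms as exchangeable points; it does
  not condition on expression levels.
- bedGraph ingestion materialises per-base dictionaries, appropriate for
  fixture-to-moderate scale, not whole-genome tracks.
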