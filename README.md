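# endzone

Analysis toolkit for nucleotide-level alternative polyadenylation: poly(A)
isoform cataloguing from 3' READS-style data, isoform-cluster statistics, and
RNA polymerase II elongation-rate sensitivity analysis, exercisable end to
end on synthetic data with recorded ground truth.

## The problem

A typical yeast gene produces dozens of 3' mRNA isoforms whose endpoints fall
in a ~200-nt "end zone" of the 3'UTR, and those endpoints cluster: groups of
isoforms spaced ≤4 nt apart. Pol II speed mutants shift poly(A) site usage —
slow derivatives shift it upstream — and the shift is continuous at the
nucleotide level *within* clusters but nearly flat *between* them. This
package implements the computational machinery to quantify all of that:

- **3' READS preprocessing** — strip the 4-nt random leader, require a
  leading T (the reverse-complemented poly(A) tail), record the T count,
  truncate (17 nt yeast / 77 nt human), and after mapping discard
  internal-priming artifacts: reads whose T count is fully explained by the
  genomic A-run immediately 3' of the mapped end. Replicates are consolidated
  and scaled to 25 million poly(A) reads.
- **Isoform catalog** — genes with ≥1000 reads; major isoforms at ≥5% of the
  gene's top isoform (human low-depth variant: ≥5 reads when the top isoform
  has <100 reads in either genotype); mutant/WT utilization
  u(p) = rel_mut(p) / rel_wt(p) over common major isoforms.
- **Cluster detection and permutation null** — maximal runs of endpoints
  with gaps ≤4 nt; per gene, the observed cluster-size pattern is compared
  with 100,000 uniform re-placements over the non-A 3'UTR positions, with an
  exact enumeration oracle for small genes and probability floor 1/100,000.
- **Speed-shift statistics** — per-cluster least-squares slope of u vs
  position (clusters of ≥4 isoforms, |Pearson R| quality gates), median
  relative ratios u_down/u_up by pair spacing within and between clusters,
  and cluster-agnostic neighboring-pair differences.
- **GC elements** — 10-nt sliding-window GC vs cluster slope correlations
  (−100..−1 and +1..+100 of cluster edges) with Benjamini–Hochberg FDR, and
  quintile analysis of GC change at +13..+30 downstream of clusters.
- **Occupancy metagenes** — single-base nascent 3'-end coverage around
  poly(A) sites and intronic AATAAA decoy anchors (±100 nt), with MAPQ
  filtering, matched downsampling, and per-position AT composition.
- **Synthetic data** — a generator producing genomes, annotations, clustered
  endpoint profiles with per-cluster geometric mutant tilt (usage reweighted
  by r^d across a cluster, a 0.98 factor per cluster boundary), optional GC
  elements at +13..+30 coupled to tilt magnitude, 3' READS reads with
  internal-priming artifacts, and occupancy tracks with an upstream dip and
  biphasic downstream increase — all with recorded truth.

## Worked example

```python
import numpy as np
import endzone as ez

genome, genes, truth = ez.make_genome(100, tilt_r=0.9, seed=7)
wt  = ez.build_catalog(ez.simulate_endpoint_counts(truth, "wt",     100_000, seed=1), ez.YEAST)
mut = ez.build_catalog(ez.simulate_endpoint_counts(truth, "mutant", 100_000, seed=2), ez.YEAST)
series  = ez.combine_genotypes(wt, mut, ez.YEAST)
records = ez.cluster_slopes(series)
within  = ez.within_cluster_spacing_medians(records, r_threshold=0.7,
                                            stat_kind="relative_ratio", max_spacing=15)
print(within.head(5).to_string(index=False))
```

```
 spacing   median  n_pairs
       1 0.905529      129
       2 0.819755      137
       3 0.738539      160
       4 0.675052      201
       5 0.615003      133
```

The median mutant/WT relative ratio of isoform pairs d nucleotides apart
tracks the generator's per-nt tilt r = 0.9 geometrically (0.9, 0.81, 0.729,
0.656, 0.59): a slow polymerase depresses each downstream isoform by a
constant factor per nucleotide. Boundary pairs between clusters instead sit
at the flat between-cluster constant:

```python
between = ez.between_cluster_spacing_medians(series)
np.median(np.repeat(between["median"], between["n_pairs"]))   # 0.981
```

And a clustered gene is exceedingly unlikely under uniform placement:

```python
res = ez.pattern_probability_for_gene(genes["g0000"], genome,
                                      truth.genes["g0000"].endpoints,
                                      n_shuffles=100_000, seed=0)
res.pattern_probability, res.neg_log10_p    # (0.00001, 5.0) -- floored
```

A `endzone` console script exposes the same stages as subcommands
(`simulate`, `preprocess`, `catalog`, `clusters`, `nullperm`, `shift`, `gc`,
`metagene`); see `endzone --help`.

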