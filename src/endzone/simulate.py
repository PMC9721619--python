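"""Synthetic genomes, poly(A) isoform profiles, 3' READS-style reads, and
nascent 3'-end coverage, with full ground truth.

The generator emulates the structure of yeast/human 3' READS data: per-gene
poly(A) endpoints grouped into clusters (intra-cluster gaps 1-4 nt,
inter-cluster gaps 35-60 nt) inside a ~200-nt 3'UTR end zone; a mutant
genotype tilts within-cluster usage geometrically (the i-th nt of a cluster
is reweighted by r^i, r<1 for slow Pol II) and applies a small constant
factor per cluster boundary; optional GC enrichment 13-30 nt downstream of
each cluster is coupled to the cluster's tilt magnitude; and single-base
occupancy tracks dip upstream of poly(A) sites and rise biphasically
downstream. Endpoints (and the base just 3' of each) are placed only on
non-A sense bases so the internal-priming filter cannot eat true signal; a
genomic A-run per gene provides an internal-priming artifact site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeSequence
from .io import EndCoverage

UPSTREAM_PAD = 150   # coding-region pad 5' of the stop codon
DOWNSTREAM_PAD = 220  # pad 3' of the UTR for GC windows / metagene flanks

_BASES = np.array(list("ACGT"))
_BASE_P = np.array([0.325, 0.175, 0.175, 0.325])  # ~35% GC background


@dataclass(frozen=True)
class OccupancyParams:
    """Multiplicative occupancy modifiers around each true poly(A) site."""

    dip_window: tuple[int, int] = (-40, -1)
    dip: float = 0.6
    bump1_window: tuple[int, int] = (10, 25)
    bump1: float = 1.5
    bump2_window: tuple[int, int] = (30, 100)
    bump2: float = 2.5
    mutant_bump2_scale: float = 1.2  # slow mutant: stronger second bump


@dataclass
class ClusterTruth:
    offsets: tuple[int, ...]      # ascending transcript offsets
    weights: tuple[float, ...]    # baseline (WT) usage weights
    tilt_exponent: float          # s: per-cluster multiplier on log r
    tilt_r: float                 # effective per-nt mutant/WT factor r**s
    gc_target: float | None       # GC fraction written at +13..+30, if any


@dataclass
class GeneTruth:
    gene_id: str
    clusters: list[ClusterTruth]
    artifact_offset: int | None = None  # non-A base 5' of the planted A-run
    artifact_run_len: int = 0

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([o for c in self.clusters for o in c.offsets],
                        dtype=int)

    def usage_weights(self, genotype: str = "wt",
                      r_override: float | None = None,
                      between_cluster_factor: float = 0.98) -> np.ndarray:
        """Per-endpoint usage weights (normalised to 1) for a genotype.

        The mutant/WT usage ratio declines geometrically (factor r_c per nt)
        across each cluster and carries over between clusters: at every
        cluster boundary it drops once by ``between_cluster_factor`` from
        the level reached at the upstream cluster's 3'-most isoform, giving
        the near-flat inter-cluster behaviour. ``r_override`` replaces the
        global tilt while keeping each cluster's exponent s, so two mutants
        of different speed share one genome.
        """
        if genotype not in ("wt", "mutant"):
            raise ValueError(f"genotype must be 'wt' or 'mutant', "
                             f"got {genotype!r}")
        parts = []
        level = 1.0  # mutant/WT ratio entering the current cluster
        for c in self.clusters:
            w = np.asarray(c.weights, dtype=float)
            if genotype == "mutant":
                r = (r_override ** c.tilt_exponent
                     if r_override is not None else c.tilt_r)
                d = np.asarray(c.offsets) - c.offsets[0]
                w = w * level * (r ** d)
                level = level * (r ** int(d[-1])) * between_cluster_factor
            parts.append(w)
        w = np.concatenate(parts) if parts else np.zeros(0)
        return w / w.sum()


@dataclass
class SyntheticTruth:
    genes: dict[str, GeneTruth]
    tilt_r: float
    tilt_spread: float
    between_cluster_factor: float
    gc_coupling: float
    gc_base: float
    occupancy: OccupancyParams = field(default_factory=OccupancyParams)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            for ci, c in enumerate(g.clusters):
                for o, w in zip(c.offsets, c.weights):
                    rows.append({
                        "gene_id": g.gene_id, "cluster_index": ci,
                        "offset": o, "weight": w,
                        "tilt_r": c.tilt_r,
                        "gc_target": c.gc_target,
                    })
        return pd.DataFrame(rows, columns=["gene_id", "cluster_index",
                                           "offset", "weight", "tilt_r",
                                           "gc_target"])


def _random_layout(rng: np.random.Generator, utr_len: int) -> list[list[int]]:
    """Random cluster member offsets for one gene, greedily fitting the UTR.

    The 5'-most cluster is the gene's dominant one (4-8 isoforms) and the
    only one large enough for slope analysis; downstream clusters are small
    (1-3 isoforms). Placing the analyzable cluster first keeps its mutant/WT
    utilization level at 1, so its slope reflects its own tilt rather than
    the decline accumulated over upstream clusters.
    """
    n_clusters = int(rng.integers(2, 4))
    sizes = np.concatenate((
        rng.integers(4, 9, size=1),
        rng.integers(1, 4, size=n_clusters - 1),
    ))
    start = int(rng.integers(15, 26))
    clusters: list[list[int]] = []
    pos = start
    for k, size in enumerate(sizes):
        gaps = rng.integers(1, 5, size=int(size) - 1)
        members = pos + np.concatenate(([0], np.cumsum(gaps)))
        if members[-1] + 30 > utr_len:
            break
        clusters.append([int(m) for m in members])
        pos = int(members[-1]) + int(rng.integers(35, 61))
    return clusters


def _spec_layout(entry, utr_len: int) -> list[list[int]]:
    """Cluster layout from an explicit spec entry: either a list of cluster
    sizes, or a list of explicit member-offset tuples."""
    clusters: list[list[int]] = []
    if entry and isinstance(entry[0], (list, tuple)):
        clusters = [sorted(int(o) for o in c) for c in entry]
    else:
        pos = 15
        for size in entry:
            members = [pos + 2 * i for i in range(int(size))]
            clusters.append(members)
            pos = members[-1] + 40
    if clusters and clusters[-1][-1] + 30 > utr_len:
        raise ValueError(
            f"cluster_spec spans to offset {clusters[-1][-1]} but utr_len "
            f"{utr_len} leaves no room for the +30 downstream margin")
    return clusters


def make_genome(n_genes: int, utr_len: int = 200, cluster_spec=None,
                gc_coupling: float = 0.0, tilt_r: float = 0.9,
                tilt_spread: float = 0.25,
                between_cluster_factor: float = 0.98, gc_base: float = 0.35,
                occupancy: OccupancyParams | None = None,
                minus_strand_fraction: float = 0.0,
                seed: int | None = None
                ) -> tuple[GenomeSequence, dict[str, GeneModel],
                           SyntheticTruth]:
    """Generate a genome (one contig per gene), gene models, and truth.

    When ``gc_coupling > 0`` the 18-nt window 13-30 nt downstream of each
    cluster's 3'-most endpoint is rewritten with GC fraction
    ``gc_base + gc_coupling*(s-1)/(2*tilt_spread)`` where s is the cluster's
    tilt exponent — clusters more sensitive to a slow mutant (s large, slope
    more negative) get proportionally more downstream GC.
    """
    rng = np.random.default_rng(seed)
    occupancy = occupancy or OccupancyParams()
    seqs: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    truth_genes: dict[str, GeneTruth] = {}
    chrom_len = UPSTREAM_PAD + utr_len + DOWNSTREAM_PAD

    for gi in range(n_genes):
        gene_id = f"g{gi:04d}"
        chrom = f"chr_{gene_id}"
        if cluster_spec is not None:
            layout = _spec_layout(cluster_spec[gi], utr_len)
        else:
            layout = _random_layout(rng, utr_len)
            if not layout:
                raise ValueError(
                    f"utr_len {utr_len} cannot hold a single cluster")
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        stop = UPSTREAM_PAD - 1 if strand == "+" else chrom_len - UPSTREAM_PAD
        gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                         stop_codon_end=stop, utr_window=(0, utr_len))
        seq = rng.choice(_BASES, size=chrom_len, p=_BASE_P)

        def put(offset: int, base: str) -> None:
            pos = gene.offset_to_genomic(offset)
            seq[pos] = base if strand == "+" else \
                {"A": "T", "C": "G", "G": "C", "T": "A"}[base]

        def get(offset: int) -> str:
            pos = gene.offset_to_genomic(offset)
            b = str(seq[pos])
            return b if strand == "+" else \
                {"A": "T", "C": "G", "G": "C", "T": "A"}[b]

        clusters: list[ClusterTruth] = []
        for members in layout:
            s = float(rng.uniform(1 - tilt_spread, 1 + tilt_spread))
            gc_target = None
            if gc_coupling > 0:
                gc_target = float(np.clip(
                    gc_base + gc_coupling * (s - 1) / (2 * tilt_spread),
                    0.05, 0.95))
                for off in range(members[-1] + 13, members[-1] + 31):
                    if rng.random() < gc_target:
                        put(off, "G" if rng.random() < 0.5 else "C")
                    else:
                        put(off, "A" if rng.random() < 0.5 else "T")
            weights = rng.lognormal(mean=0.0, sigma=0.5, size=len(members))
            clusters.append(ClusterTruth(
                offsets=tuple(members),
                weights=tuple(float(w) for w in weights),
                tilt_exponent=s, tilt_r=float(tilt_r ** s),
                gc_target=gc_target))

        # endpoints and the base just 3' of each must be non-A on the sense
        # strand, or the internal-priming filter would discard true reads;
        # A -> T keeps the substitution GC-neutral (and poly(A) sites sit in
        # AU-rich context), so forced bases cannot leak into GC statistics
        for c in clusters:
            for off in c.offsets:
                for o in (off, off + 1):
                    if get(o) == "A":
                        put(o, "T")

        # plant one genomic A-run as an internal-priming artifact site
        artifact_offset, run_len = None, 0
        first, last = clusters[0].offsets[0], clusters[-1].offsets[-1]
        run_len = 8
        if first >= 14:
            site = first - 12
        elif last + 40 + run_len + 1 <= utr_len:
            site = last + 40
        else:
            site = None
        if site is not None:
            if get(site) == "A":
                put(site, "T")
            for o in range(site + 1, site + 1 + run_len):
                put(o, "A")
            # terminate the run crisply
            if get(site + run_len + 1) == "A":
                put(site + run_len + 1, "T")
            artifact_offset = site

        seqs[chrom] = "".join(seq)
        genes[gene_id] = gene
        truth_genes[gene_id] = GeneTruth(
            gene_id=gene_id, clusters=clusters,
            artifact_offset=artifact_offset, artifact_run_len=run_len)

    truth = SyntheticTruth(
        genes=truth_genes, tilt_r=tilt_r, tilt_spread=tilt_spread,
        between_cluster_factor=between_cluster_factor,
        gc_coupling=gc_coupling, gc_base=gc_base, occupancy=occupancy)
    return GenomeSequence(seqs), genes, truth


# ---------------------------------------------------------------------------
# Endpoint-count simulation (direct multinomial route)


def simulate_endpoint_counts(truth: SyntheticTruth, genotype: str = "wt",
                             depth: int = 100_000,
                             r_override: float | None = None,
                             seed: int | None = None) -> pd.DataFrame:
    """Multinomial endpoint counts per gene at ``depth`` reads/gene,
    bypassing read-level simulation. Returns (gene_id, offset, count)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in truth.genes.values():
        w = g.usage_weights(genotype, r_override,
                            truth.between_cluster_factor)
        counts = rng.multinomial(depth, w)
        for off, n in zip(g.endpoints, counts):
            if n > 0:
                rows.append({"gene_id": g.gene_id, "offset": int(off),
                             "count": float(n)})
    return pd.DataFrame(rows, columns=["gene_id", "offset", "count"])


# ---------------------------------------------------------------------------
# Read-level simulation (FASTQ route)


def simulate_polya_reads(truth: SyntheticTruth,
                         genes: dict[str, GeneModel],
                         genome: GenomeSequence, genotype: str = "wt",
                         depth: int = 1000, artifact_rate: float = 0.0,
                         tail_mean: float = 8.0, frag_len: int = 25,
                         r_override: float | None = None,
                         seed: int | None = None
                         ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """3' READS-style reads: 4 random nt, a leading T-run (the reverse-
    complemented poly(A) tail, length 1+Geom with the given mean), then the
    reverse complement of the sense strand ending at the endpoint.

    With probability ``artifact_rate`` a read is an internal-priming
    artifact: its 3' end sits just 5' of the gene's planted genomic A-run and
    its T count never exceeds the run length, so the genomic As fully explain
    the tail. Returns (reads, truth BED table).
    """
    if not 0 <= artifact_rate < 1:
        raise ValueError("artifact_rate must be in [0, 1)")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    p_tail = 1.0 / tail_mean
    reads: list[tuple[str, str]] = []
    bed_rows = []
    for g in truth.genes.values():
        gene = genes[g.gene_id]
        endpoints = g.endpoints
        w = g.usage_weights(genotype, r_override,
                            truth.between_cluster_factor)
        can_artifact = g.artifact_offset is not None and artifact_rate > 0
        for i in range(depth):
            is_artifact = can_artifact and rng.random() < artifact_rate
            if is_artifact:
                off = g.artifact_offset
                t = int(rng.integers(1, g.artifact_run_len + 1))
            else:
                off = int(endpoints[rng.choice(endpoints.size, p=w)])
                t = int(rng.geometric(p_tail))
            sense = gene.fetch_offsets(genome, off - frag_len + 1, off)
            rc = sense.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
            lead = "".join(rng.choice(_BASES, size=4))
            rid = (f"{g.gene_id}|{off}|"
                   f"{'artifact' if is_artifact else 'true'}|{i}")
            reads.append((rid, lead + "T" * t + rc))
            bed_rows.append({
                "chrom": gene.chrom, "pos": gene.offset_to_genomic(off),
                "strand": gene.strand, "t_count": t, "read_id": rid,
                "gene_id": g.gene_id, "offset": off,
                "artifact": is_artifact})
    bed = pd.DataFrame(bed_rows, columns=["chrom", "pos", "strand", "t_count",
                                          "read_id", "gene_id", "offset",
                                          "artifact"])
    return reads, bed


# ---------------------------------------------------------------------------
# Nascent 3'-end (occupancy) simulation


def simulate_enetseq(truth: SyntheticTruth, genes: dict[str, GeneModel],
                     genome: GenomeSequence, genotype: str = "wt",
                     depth: int = 1_000_000,
                     seed: int | None = None) -> EndCoverage:
    """Single-base nascent 3'-end coverage: Poisson counts around an expected
    profile that is flat except for a dip upstream and two bumps downstream
    of every true poly(A) endpoint (multiplicative, per endpoint).

    ``depth`` is the expected read total per gene.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    occ = truth.occupancy
    cov = EndCoverage()
    if depth == 0:
        return cov
    bump2 = occ.bump2 * (occ.mutant_bump2_scale if genotype == "mutant"
                         else 1.0)
    for g in truth.genes.values():
        gene = genes[g.gene_id]
        utr_len = gene.utr_window[1]
        lo, hi = -(UPSTREAM_PAD - 1), utr_len + DOWNSTREAM_PAD - 1
        offsets = np.arange(lo, hi + 1)
        expected = np.ones(offsets.size, dtype=float)
        for e in g.endpoints:
            for (a, b), amp in ((occ.dip_window, occ.dip),
                                (occ.bump1_window, occ.bump1),
                                (occ.bump2_window, bump2)):
                sel = (offsets >= e + a) & (offsets <= e + b)
                expected[sel] *= amp
        lam = expected / expected.sum() * depth
        counts = rng.poisson(lam)
        for off, n in zip(offsets, counts):
            if n > 0:
                cov.add(gene.chrom, gene.offset_to_genomic(int(off)),
                        gene.strand, int(n))
    return cov


# ---------------------------------------------------------------------------
# Decoy-site fixtures: long introns with AATAAA hexamers, flat coverage


def make_intron_genome(n_introns: int = 2, intron_len: int = 12_000,
                       hexamers_per_intron: int = 4,
                       seed: int | None = None
                       ) -> tuple[GenomeSequence, pd.DataFrame, list[tuple]]:
    """Random long introns with planted sense-strand AATAAA hexamers.

    Returns (genome, intron table (chrom, start, end, strand, length),
    planted hexamer sites as (chrom, hexamer_start, strand)).
    """
    rng = np.random.default_rng(seed)
    seqs, rows, planted = {}, [], []
    for i in range(n_introns):
        chrom = f"intron_{i}"
        seq = rng.choice(_BASES, size=intron_len, p=_BASE_P)
        starts = np.linspace(300, intron_len - 300, hexamers_per_intron,
                             dtype=int)
        for s in starts:
            seq[s:s + 6] = list("AATAAA")
            planted.append((chrom, int(s), "+"))
        seqs[chrom] = "".join(seq)
        rows.append({"chrom": chrom, "start": 0, "end": intron_len,
                     "strand": "+", "length": intron_len})
    introns = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                          "length"])
    return GenomeSequence(seqs), introns, planted


def simulate_flat_coverage(regions: pd.DataFrame, rate: float,
                           seed: int | None = None) -> EndCoverage:
    """Bump-free Poisson coverage at ``rate`` expected reads/base over each
    region (chrom, start, end, strand)."""
    rng = np.random.default_rng(seed)
    cov = EndCoverage()
    for row in regions.itertuples(index=False):
        counts = rng.poisson(rate, size=int(row.end) - int(row.start))
        for pos, n in zip(range(int(row.start), int(row.end)), counts):
            if n > 0:
                cov.add(row.chrom, pos, row.strand, int(n))
    return cov
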