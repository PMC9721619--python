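"""Per-gene isoform tables, major-isoform selection, and mutant/WT
utilization.

"Relative expression" of an isoform is its scaled read count divided by the
gene's total over the retained (major) isoforms of the same genotype; the
utilization ratio u(p) divides the mutant's relative expression at endpoint p
by the wild type's. Any gene-constant denominator yields the same downstream
ratio-of-ratio and slope statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SpeciesProfile, YEAST


@dataclass
class IsoformTable:
    gene_id: str
    offsets: np.ndarray          # ascending transcript offsets
    counts: np.ndarray           # scaled counts, same order
    major: np.ndarray | None = None  # bool mask after major selection

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.offsets.size and np.any(np.diff(self.offsets) <= 0):
            raise ValueError(f"{self.gene_id}: offsets must be strictly "
                             "increasing")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def max_count(self) -> float:
        return float(self.counts.max()) if self.counts.size else 0.0

    def major_offsets(self) -> np.ndarray:
        if self.major is None:
            raise ValueError("major isoforms not selected yet")
        return self.offsets[self.major]

    def major_counts(self) -> np.ndarray:
        if self.major is None:
            raise ValueError("major isoforms not selected yet")
        return self.counts[self.major]


@dataclass
class UtilizationSeries:
    """Common-major isoforms of one gene with mutant/WT utilization ratios."""

    gene_id: str
    offsets: np.ndarray
    count_wt: np.ndarray
    count_mut: np.ndarray
    rel_wt: np.ndarray
    rel_mut: np.ndarray
    u: np.ndarray  # rel_mut / rel_wt, > 0


def endpoint_counts_to_catalog(endpoints: pd.DataFrame,
                               profile: SpeciesProfile = YEAST
                               ) -> dict[str, IsoformTable]:
    """Group an endpoint count table (gene_id, offset, count) into per-gene
    isoform tables, dropping genes below the profile's read floor."""
    catalog: dict[str, IsoformTable] = {}
    if endpoints.empty:
        return catalog
    grouped = endpoints.groupby("gene_id", sort=True)
    for gene_id, sub in grouped:
        agg = sub.groupby("offset", sort=True)["count"].sum()
        if agg.sum() < profile.gene_min_reads:
            continue
        catalog[gene_id] = IsoformTable(
            gene_id=gene_id,
            offsets=agg.index.to_numpy(),
            counts=agg.to_numpy(),
        )
    return catalog


build_catalog = endpoint_counts_to_catalog


def select_major_isoforms(table: IsoformTable,
                          profile: SpeciesProfile = YEAST,
                          other_max_count: float | None = None
                          ) -> IsoformTable:
    """Flag major isoforms.

    Yeast: major iff count >= 5% of the gene's maximally expressed isoform
    (strict > behind ``major_fraction_strict``). Human low-depth rule: if the
    maximum isoform holds <100 reads in either genotype (``other_max_count``
    carries the partner genotype's maximum), majors are isoforms with >=5
    reads; otherwise majors must strictly exceed 5% of the maximum.
    """
    if table.offsets.size == 0:
        raise ValueError(f"{table.gene_id}: empty isoform table")
    mx = table.max_count
    low_depth = (
        profile.low_depth_max_isoform is not None
        and (mx < profile.low_depth_max_isoform
             or (other_max_count is not None
                 and other_max_count < profile.low_depth_max_isoform))
    )
    if low_depth:
        mask = table.counts >= profile.low_depth_min_reads
    else:
        thr = profile.major_isoform_fraction * mx
        mask = table.counts > thr if profile.major_fraction_strict \
            else table.counts >= thr
    out = IsoformTable(table.gene_id, table.offsets.copy(),
                       table.counts.copy())
    out.major = mask
    return out


def major_mass_fraction(catalog: dict[str, IsoformTable]) -> float:
    """Fraction of scaled read mass carried by major isoforms."""
    tot = sum(t.total for t in catalog.values())
    if tot == 0:
        return float("nan")
    majors = sum(float(t.major_counts().sum()) for t in catalog.values())
    return majors / tot


def combine_genotypes(wt: dict[str, IsoformTable],
                      mut: dict[str, IsoformTable],
                      profile: SpeciesProfile = YEAST
                      ) -> dict[str, UtilizationSeries]:
    """Join two genotype catalogs on isoforms major in both, computing the
    mutant/WT utilization ratio per common major isoform.

    Genes with fewer than two common majors are dropped. Major flags are
    (re)computed here so the human low-depth rule can see both genotypes'
    maximum isoform counts.
    """
    series: dict[str, UtilizationSeries] = {}
    for gene_id in sorted(set(wt) & set(mut)):
        twt, tmut = wt[gene_id], mut[gene_id]
        fwt = select_major_isoforms(twt, profile,
                                    other_max_count=tmut.max_count)
        fmut = select_major_isoforms(tmut, profile,
                                     other_max_count=twt.max_count)
        common = np.intersect1d(fwt.major_offsets(), fmut.major_offsets())
        if common.size < 2:
            continue
        iw = np.searchsorted(fwt.offsets, common)
        im = np.searchsorted(fmut.offsets, common)
        cwt = fwt.counts[iw]
        cmut = fmut.counts[im]
        rel_wt = cwt / cwt.sum()
        rel_mut = cmut / cmut.sum()
        series[gene_id] = UtilizationSeries(
            gene_id=gene_id, offsets=common, count_wt=cwt, count_mut=cmut,
            rel_wt=rel_wt, rel_mut=rel_mut, u=rel_mut / rel_wt)
    return series


def series_to_frame(series: dict[str, UtilizationSeries]) -> pd.DataFrame:
    rows = []
    for s in series.values():
        for i in range(s.offsets.size):
            rows.append({
                "gene_id": s.gene_id, "offset": int(s.offsets[i]),
                "count_wt": s.count_wt[i], "count_mut": s.count_mut[i],
                "rel_wt": s.rel_wt[i], "rel_mut": s.rel_mut[i],
                "u": s.u[i],
            })
    return pd.DataFrame(rows, columns=["gene_id", "offset", "count_wt",
                                       "count_mut", "rel_wt", "rel_mut", "u"])
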