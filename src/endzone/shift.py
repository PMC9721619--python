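"""Elongation-rate sensitivity statistics.

Within clusters of four or more common major isoforms, the least-squares
slope of the mutant/WT utilization ratio u against endpoint position (with
its Pearson R as a quality gate) quantifies the nucleotide-level shift; slow
Pol II mutants give negative slopes, fast mutants positive ones. Spacing
medians summarise pairwise shifts within clusters, across cluster boundaries,
and over cluster-agnostic neighboring pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import UtilizationSeries
from .clusters import Cluster, detect_clusters

STAT_KINDS = ("relative_ratio", "percent_difference", "difference")


@dataclass
class SlopeRecord:
    gene_id: str
    cluster_index: int
    members: tuple[int, ...]
    u: tuple[float, ...]
    slope: float
    pearson_r: float  # NaN when u has zero variance
    n_isoforms: int

    @property
    def gated(self) -> bool:
        return np.isfinite(self.pearson_r)

    @property
    def five_prime_most(self) -> int:
        return self.members[0]

    @property
    def three_prime_most(self) -> int:
        return self.members[-1]


def _pair_stat(u_up: float, u_down: float, stat_kind: str) -> float:
    if stat_kind == "relative_ratio":
        return u_down / u_up
    if stat_kind == "percent_difference":
        return 100.0 * (u_down - u_up) / u_up
    if stat_kind == "difference":
        return u_down - u_up
    raise ValueError(f"unknown stat_kind {stat_kind!r}; one of {STAT_KINDS}")


def cluster_slopes(series: dict[str, UtilizationSeries], max_gap: int = 4,
                   min_isoforms: int = 4) -> list[SlopeRecord]:
    """Least-squares slope and Pearson R of u vs offset per cluster with
    >= min_isoforms isoforms; constant-u clusters get R = NaN (flagged)."""
    records: list[SlopeRecord] = []
    for gene_id, s in series.items():
        clusters = detect_clusters(s.offsets, max_gap, gene_id=gene_id)
        pos = {int(o): i for i, o in enumerate(s.offsets)}
        for ci, c in enumerate(clusters):
            if c.size < min_isoforms:
                continue
            x = np.array(c.members, dtype=float)
            y = np.array([s.u[pos[o]] for o in c.members], dtype=float)
            slope = float(np.polyfit(x, y, 1)[0])
            if np.ptp(y) == 0:
                r = float("nan")
            else:
                r = float(stats.pearsonr(x, y)[0])
            records.append(SlopeRecord(
                gene_id=gene_id, cluster_index=ci, members=c.members,
                u=tuple(float(v) for v in y), slope=slope, pearson_r=r,
                n_isoforms=c.size))
    return records


def slopes_to_frame(records: list[SlopeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "cluster_index": r.cluster_index,
                "start": r.five_prime_most, "end": r.three_prime_most,
                "n_isoforms": r.n_isoforms, "slope": r.slope,
                "pearson_r": r.pearson_r,
            }
            for r in records
        ],
        columns=["gene_id", "cluster_index", "start", "end", "n_isoforms",
                 "slope", "pearson_r"])


def _medians_frame(stats_by_spacing: dict[int, list[float]]) -> pd.DataFrame:
    rows = [
        {"spacing": d, "median": float(np.median(v)), "n_pairs": len(v)}
        for d, v in sorted(stats_by_spacing.items()) if v
    ]
    return pd.DataFrame(rows, columns=["spacing", "median", "n_pairs"])


def within_cluster_spacing_medians(records: list[SlopeRecord],
                                   r_threshold: float = 0.7,
                                   stat_kind: str = "relative_ratio",
                                   max_spacing: int = 15) -> pd.DataFrame:
    """Median pair statistic by spacing over all ordered isoform pairs
    (adjacent or not) inside clusters passing the |R| quality gate."""
    by_spacing: dict[int, list[float]] = {}
    for rec in records:
        if not rec.gated or abs(rec.pearson_r) <= r_threshold:
            continue
        m, u = rec.members, rec.u
        for i in range(len(m)):
            for j in range(i + 1, len(m)):
                d = m[j] - m[i]
                if d > max_spacing:
                    continue
                by_spacing.setdefault(d, []).append(
                    _pair_stat(u[i], u[j], stat_kind))
    return _medians_frame(by_spacing)


def between_cluster_spacing_medians(series: dict[str, UtilizationSeries],
                                    max_gap: int = 4,
                                    stat_kind: str = "relative_ratio",
                                    min_cluster_size: int = 1,
                                    max_distance: int | None = None
                                    ) -> pd.DataFrame:
    """Median pair statistic by inter-cluster distance over adjacent cluster
    boundary pairs (3'-most isoform of the upstream cluster vs 5'-most of the
    downstream one). ``min_cluster_size`` optionally drops boundary pairs
    touching small clusters."""
    by_distance: dict[int, list[float]] = {}
    for gene_id, s in series.items():
        clusters = detect_clusters(s.offsets, max_gap, gene_id=gene_id)
        clusters = [c for c in clusters if c.size >= min_cluster_size]
        if len(clusters) < 2:
            continue
        pos = {int(o): i for i, o in enumerate(s.offsets)}
        for up, down in zip(clusters[:-1], clusters[1:]):
            a, b = up.three_prime_most, down.five_prime_most
            d = b - a
            if max_distance is not None and d > max_distance:
                continue
            by_distance.setdefault(d, []).append(
                _pair_stat(s.u[pos[a]], s.u[pos[b]], stat_kind))
    return _medians_frame(by_distance)


def neighboring_pair_differences(series: dict[str, UtilizationSeries],
                                 stat_kind: str = "difference",
                                 max_spacing: int | None = None
                                 ) -> pd.DataFrame:
    """Cluster-agnostic analysis: for every pair of neighboring common major
    isoforms (no other major isoform between them), the downstream-minus-
    upstream utilization statistic, medianed by spacing."""
    by_spacing: dict[int, list[float]] = {}
    for s in series.values():
        for i in range(s.offsets.size - 1):
            d = int(s.offsets[i + 1] - s.offsets[i])
            if max_spacing is not None and d > max_spacing:
                continue
            by_spacing.setdefault(d, []).append(
                _pair_stat(float(s.u[i]), float(s.u[i + 1]), stat_kind))
    return _medians_frame(by_spacing)
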