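"""Isoform cluster detection and genome-wide cluster-size tabulation.

A cluster is a maximal run of poly(A) isoform 3' endpoints in which each
endpoint is no more than ``max_gap`` nucleotides (default 4) from the next;
isolated endpoints form single-isoform clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Cluster:
    gene_id: str
    members: tuple[int, ...]  # ascending transcript offsets

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def five_prime_most(self) -> int:
        return self.members[0]

    @property
    def three_prime_most(self) -> int:
        return self.members[-1]


ClusterPattern = Counter  # cluster size -> number of clusters of that size


def detect_clusters(offsets, max_gap: int = 4,
                    gene_id: str = "") -> list[Cluster]:
    """Partition strictly increasing endpoint offsets into maximal runs with
    consecutive differences <= max_gap."""
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    offs = np.asarray(offsets, dtype=int)
    if offs.size == 0:
        return []
    if np.any(np.diff(offs) <= 0):
        raise ValueError("offsets must be strictly increasing")
    breaks = np.flatnonzero(np.diff(offs) > max_gap)
    bounds = np.concatenate(([0], breaks + 1, [offs.size]))
    return [
        Cluster(gene_id=gene_id, members=tuple(int(o) for o in offs[a:b]))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def pattern_of(clusters: list[Cluster]) -> ClusterPattern:
    """Size histogram of one gene's clusters."""
    return Counter(c.size for c in clusters)


def pattern_key(pattern: ClusterPattern) -> tuple[int, ...]:
    """Canonical form of a pattern: the sorted multiset of cluster sizes."""
    return tuple(sorted(s for s, n in pattern.items() for _ in range(n)))


def genomewide_frequencies(patterns, max_size_bin: int = 20) -> pd.DataFrame:
    """Combine per-gene cluster patterns into a size -> percentage table.

    Sizes above ``max_size_bin`` are pooled into a single '>N' bin, matching
    the 1..20 plus '>20' presentation. Percentages sum to 100.
    """
    combined: Counter = Counter()
    for p in patterns:
        combined.update(p)
    total = sum(combined.values())
    if total == 0:
        return pd.DataFrame(columns=["size", "count", "percent"])
    rows = []
    over = 0
    for size in sorted(combined):
        if size > max_size_bin:
            over += combined[size]
        else:
            rows.append((str(size), combined[size]))
    if over:
        rows.append((f">{max_size_bin}", over))
    df = pd.DataFrame(rows, columns=["size", "count"])
    df["percent"] = 100.0 * df["count"] / total
    return df


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "cluster_index": i,
            "start": c.five_prime_most,
            "end": c.three_prime_most,
            "size": c.size,
            "members": ",".join(map(str, c.members)),
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "cluster_index", "start", "end", "size",
                       "members"])
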