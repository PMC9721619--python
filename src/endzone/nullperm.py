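"""Permutation null for cluster patterns.

For each gene the observed major isoforms are repeatedly re-placed uniformly
at random (without replacement) over the non-A positions of its 3'UTR; the
probability of the observed cluster-size pattern is the fraction of shuffles
reproducing it exactly, floored at 1/n_shuffles when no shuffle matches.
An exact enumeration oracle is provided for small genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .clusters import ClusterPattern, detect_clusters, pattern_key, pattern_of
from .genome import GeneModel, GenomeSequence


def eligible_positions(gene: GeneModel, genome: GenomeSequence) -> np.ndarray:
    """Transcript offsets within the 3'UTR whose sense-strand base is not A.

    Genomically encoded terminal As are indistinguishable from poly(A)-tail
    As, so A positions can never be called as endpoints.
    """
    down = gene.utr_window[1]
    seq = gene.fetch_offsets(genome, 1, down)
    return np.array([i + 1 for i, b in enumerate(seq) if b != "A"], dtype=int)


@dataclass
class ShuffleResult:
    gene_id: str
    n_isoforms: int
    n_shuffles: int
    n_pattern_matches: int
    pattern_probability: float
    floored: bool
    null_size_counts: Counter = field(default_factory=Counter)

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.pattern_probability))


def _run_sizes(sorted_positions: np.ndarray, max_gap: int) -> tuple[int, ...]:
    """Sorted multiset of maximal-run sizes of an ascending position array."""
    k = sorted_positions.size
    if k == 0:
        return ()
    breaks = np.flatnonzero(np.diff(sorted_positions) > max_gap)
    bounds = np.concatenate(([0], breaks + 1, [k]))
    return tuple(sorted((bounds[1:] - bounds[:-1]).tolist()))


def pattern_probability(observed: ClusterPattern, eligible: np.ndarray,
                        n_isoforms: int, n_shuffles: int = 100_000,
                        max_gap: int = 4, seed: int | None = None,
                        gene_id: str = "", chunk: int = 20_000
                        ) -> ShuffleResult:
    """Monte-Carlo probability that the observed cluster pattern arises from
    uniform placement of ``n_isoforms`` endpoints on ``eligible`` positions."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    elig = np.sort(np.asarray(eligible, dtype=int))
    m, k = elig.size, n_isoforms
    if k > m:
        raise ValueError(
            f"{gene_id or 'gene'}: {k} isoforms but only {m} eligible "
            "positions")
    if k < 1:
        raise ValueError("n_isoforms must be >= 1")
    obs_key = pattern_key(observed)
    rng = np.random.default_rng(seed)
    matches = 0
    null_sizes: Counter = Counter()
    done = 0
    while done < n_shuffles:
        c = min(chunk, n_shuffles - done)
        # k-subsets without replacement: indices of the k smallest uniforms
        u = rng.random((c, m))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k] if k < m else \
            np.tile(np.arange(m), (c, 1))
        pos = np.sort(elig[idx], axis=1)
        gaps = np.diff(pos, axis=1) > max_gap
        for row in range(c):
            breaks = np.flatnonzero(gaps[row])
            bounds = np.concatenate(([0], breaks + 1, [k]))
            sizes = tuple(sorted((bounds[1:] - bounds[:-1]).tolist()))
            null_sizes.update(sizes)
            if sizes == obs_key:
                matches += 1
        done += c
    floored = matches == 0
    p = max(matches, 1) / n_shuffles
    return ShuffleResult(
        gene_id=gene_id, n_isoforms=k, n_shuffles=n_shuffles,
        n_pattern_matches=matches, pattern_probability=p, floored=floored,
        null_size_counts=null_sizes)


def pattern_probability_for_gene(gene: GeneModel, genome: GenomeSequence,
                                 observed_offsets, n_shuffles: int = 100_000,
                                 max_gap: int = 4, seed: int | None = None
                                 ) -> ShuffleResult:
    """Convenience wrapper: derive eligible positions and the observed
    pattern from a gene's major-isoform offsets."""
    clusters = detect_clusters(observed_offsets, max_gap, gene_id=gene.gene_id)
    observed = pattern_of(clusters)
    elig = eligible_positions(gene, genome)
    return pattern_probability(
        observed, elig, n_isoforms=len(list(observed_offsets)),
        n_shuffles=n_shuffles, max_gap=max_gap, seed=seed,
        gene_id=gene.gene_id)


def exact_pattern_probability(observed: ClusterPattern, eligible,
                              n_isoforms: int, max_gap: int = 4,
                              budget: int = 1_000_000) -> float:
    """Exact fraction of all k-subsets of eligible positions whose cluster
    pattern equals the observed one (enumeration oracle)."""
    elig = sorted(int(p) for p in eligible)
    total = comb(len(elig), n_isoforms)
    if total > budget:
        raise ValueError(
            f"C({len(elig)},{n_isoforms})={total} exceeds budget {budget}")
    obs_key = pattern_key(observed)
    hits = sum(
        1 for subset in combinations(elig, n_isoforms)
        if _run_sizes(np.array(subset), max_gap) == obs_key
    )
    return hits / total


def aggregate_null(results: list[ShuffleResult],
                   max_size_bin: int = 20) -> pd.DataFrame:
    """Combine per-gene null cluster-size counts across genes and shuffles
    into a size -> percentage table."""
    if not results:
        raise ValueError("no shuffle results to aggregate")
    combined: Counter = Counter()
    for r in results:
        combined.update(r.null_size_counts)
    total = sum(combined.values())
    rows, over = [], 0
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


def results_to_frame(results: list[ShuffleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_isoforms": r.n_isoforms,
                "n_matches": r.n_pattern_matches,
                "p": r.pattern_probability,
                "neg_log10_p": r.neg_log10_p,
                "floored": r.floored,
            }
            for r in results
        ]
    )
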