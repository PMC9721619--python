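"""Single-base Pol II occupancy metagenes around poly(A) and decoy sites.

Nascent 3'-end reads are collapsed to their RNA 3'-end base (MAPQ > 10),
libraries are downsampled to a common total, anchor sites (READS poly(A)
sites, or intronic AATAAA decoys re-centred so the hexamer sits at −25..−20
of a nominal cleavage site) are filtered on per-library read support, and
per-offset signal and AT base composition are aggregated over a ±100-nt
flank, offsets increasing in the transcript direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .io import EndCoverage


@dataclass(frozen=True)
class AnchorSite:
    chrom: str
    pos: int      # genomic coordinate of the (decoy) cleavage site
    strand: str
    site_class: str  # 'polyA' or 'decoy'


def collapse_reads(reads: pd.DataFrame, min_mapq: int = 10,
                   gene_regions: pd.DataFrame | None = None,
                   gene_flank: int = 5000,
                   exclude_regions: pd.DataFrame | None = None
                   ) -> EndCoverage:
    """Collapse mapped nascent reads (chrom, start, end, strand, mapq) to
    single-base RNA 3'-end coverage, keeping MAPQ strictly > ``min_mapq``.

    Optionally keep only reads within ``gene_flank`` of a region in
    ``gene_regions`` (protein-coding genes) and drop reads inside
    ``exclude_regions`` (e.g. snoRNAs); both tables need chrom/start/end.
    """
    cov = EndCoverage()
    for row in reads.itertuples(index=False):
        if row.mapq <= min_mapq:
            continue
        pos = int(row.end) - 1 if row.strand == "+" else int(row.start)
        if gene_regions is not None:
            near = gene_regions[
                (gene_regions["chrom"] == row.chrom)
                & (gene_regions["start"] - gene_flank <= pos)
                & (gene_regions["end"] + gene_flank > pos)]
            if near.empty:
                continue
        if exclude_regions is not None:
            inside = exclude_regions[
                (exclude_regions["chrom"] == row.chrom)
                & (exclude_regions["start"] <= pos)
                & (exclude_regions["end"] > pos)]
            if not inside.empty:
                continue
        cov.add(row.chrom, pos, row.strand)
    return cov


def downsample_matched(tracks: dict[str, EndCoverage],
                       seed: int | None = None) -> dict[str, EndCoverage]:
    """Subsample each library without replacement to the smallest library
    total, so compared libraries hold equal read counts."""
    if len(tracks) < 2:
        raise ValueError("need at least two libraries to match")
    totals = {name: int(round(t.total())) for name, t in tracks.items()}
    target = min(totals.values())
    rng = np.random.default_rng(seed)
    out: dict[str, EndCoverage] = {}
    for name, track in tracks.items():
        if totals[name] == target:
            out[name] = track
            continue
        keys, counts = [], []
        for chrom, pos, strand, c in track.items():
            keys.append((chrom, pos, strand))
            counts.append(int(round(c)))
        sub = rng.multivariate_hypergeometric(np.array(counts), target,
                                              method="marginals")
        new = EndCoverage()
        for (chrom, pos, strand), c in zip(keys, sub):
            if c > 0:
                new.add(chrom, pos, strand, int(c))
        out[name] = new
    return out


def _window_sums(cov: EndCoverage, chrom: str, pos: int, strand: str,
                 flank: int) -> tuple[float, float]:
    """(total in ±flank, total in the first ``flank`` nt downstream)."""
    total = cov.window_sum(chrom, strand, pos - flank, pos + flank)
    if strand == "+":
        down = cov.window_sum(chrom, strand, pos + 1, pos + flank)
    else:
        down = cov.window_sum(chrom, strand, pos - flank, pos - 1)
    return total, down


def select_polya_anchors(sites: pd.DataFrame,
                         tracks: dict[str, EndCoverage],
                         min_reads: int = 20, flank: int = 100
                         ) -> list[AnchorSite]:
    """Poly(A) sites with >= min_reads within ±flank and >= 1 read in the
    first ``flank`` nt downstream, in every library."""
    anchors = []
    for row in sites.itertuples(index=False):
        ok = True
        for cov in tracks.values():
            total, down = _window_sums(cov, row.chrom, int(row.pos),
                                       row.strand, flank)
            if total < min_reads or down < 1:
                ok = False
                break
        if ok:
            anchors.append(AnchorSite(row.chrom, int(row.pos), row.strand,
                                      "polyA"))
    return anchors


def find_decoy_anchors(genome: GenomeSequence, introns: pd.DataFrame,
                       tracks: dict[str, EndCoverage],
                       min_reads: int = 10, flank: int = 100,
                       min_intron_len: int = 10_000,
                       hexamer: str = "AATAAA") -> list[AnchorSite]:
    """Decoy cleavage anchors from sense-strand AATAAA matches in introns
    strictly longer than ``min_intron_len``.

    The anchor is placed 25 nt downstream (transcript direction) of the
    hexamer's 5' base, so the hexamer occupies −25..−20 relative to the
    anchor. Anchors need >= min_reads within ±flank and a non-zero read count
    in the first ``flank`` nt downstream, in every library.
    """
    anchors = []
    for row in introns.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end - start <= min_intron_len:
            continue
        sense = genome.fetch(row.chrom, start, end, row.strand)
        i = sense.find(hexamer)
        while i != -1:
            anchor_sense = i + 25
            if row.strand == "+":
                pos = start + anchor_sense
            else:
                pos = end - 1 - anchor_sense
            if start <= pos < end:
                ok = True
                for cov in tracks.values():
                    total, down = _window_sums(cov, row.chrom, pos,
                                               row.strand, flank)
                    if total < min_reads or down == 0:
                        ok = False
                        break
                if ok:
                    anchors.append(AnchorSite(row.chrom, pos, row.strand,
                                              "decoy"))
            i = sense.find(hexamer, i + 1)
    return anchors


@dataclass
class MetageneProfile:
    offsets: np.ndarray                 # −flank..+flank
    signal: dict[str, np.ndarray]       # per library
    at_percent: np.ndarray              # % of anchors with A/T per offset
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets})
        for name, arr in self.signal.items():
            df[f"signal_{name}"] = arr
        df["at_percent"] = self.at_percent
        return df


def build_metagene(anchors: list[AnchorSite],
                   tracks: dict[str, EndCoverage], genome: GenomeSequence,
                   flank: int = 100, stat: str = "sum") -> MetageneProfile:
    """Aggregate strand-oriented coverage and AT composition over anchors.

    ``stat='sum'`` totals coverage per offset across anchors; ``'mean'``
    divides by the anchor count. Anchors whose ±flank leaves the contig are
    dropped.
    """
    if not anchors:
        raise ValueError("no anchor sites")
    if stat not in ("sum", "mean"):
        raise ValueError("stat must be 'sum' or 'mean'")
    offsets = np.arange(-flank, flank + 1)
    usable = [
        a for a in anchors
        if a.pos - flank >= 0 and a.pos + flank < genome.length(a.chrom)
    ]
    if not usable:
        raise ValueError("all anchors fall off their contigs")
    signal = {name: np.zeros(offsets.size) for name in tracks}
    at = np.zeros(offsets.size)
    for a in usable:
        step = 1 if a.strand == "+" else -1
        seq = genome.fetch(a.chrom, a.pos - flank, a.pos + flank + 1,
                           a.strand)
        at += np.array([b in "AT" for b in seq], dtype=float)
        for name, cov in tracks.items():
            track = cov._data.get((a.chrom, a.strand), {})
            for k, off in enumerate(offsets):
                c = track.get(a.pos + step * int(off), 0)
                if c:
                    signal[name][k] += c
    n = len(usable)
    if stat == "mean":
        signal = {k: v / n for k, v in signal.items()}
    return MetageneProfile(offsets=offsets, signal=signal,
                           at_percent=100.0 * at / n, n_anchors=n)
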