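"""Readers and writers for the formats the pipeline touches.

FASTA genomes (Biopython), annotation TSVs, BED-like mapped 3'-end endpoint
tables, and stranded single-base bedGraph coverage. All round-trips are
lossless for valid inputs.
"""

from __future__ import annotations

import os
from collections import defaultdict

import pandas as pd
from Bio import SeqIO

from .config import SpeciesProfile, YEAST
from .genome import GeneModel, GenomeSequence

# ---------------------------------------------------------------------------
# FASTA


def load_genome(path: str | os.PathLike) -> GenomeSequence:
    """Load a FASTA genome into memory.

    Raises on empty files, duplicate record ids, and records with no sequence.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} in {path} is empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"FASTA record {rec.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str | os.PathLike,
                 width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV

_ANN_COLS = ["gene_id", "chrom", "strand", "stop_codon_end"]


def load_annotation(path: str | os.PathLike,
                    profile: SpeciesProfile = YEAST) -> dict[str, GeneModel]:
    """Read a gene annotation TSV into GeneModels.

    Required columns: gene_id, chrom, strand, stop_codon_end. Optional
    upstream_extent / downstream_extent override the profile's 3'UTR window.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "strand": str})
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        up = getattr(row, "upstream_extent", None)
        down = getattr(row, "downstream_extent", None)
        window = (
            int(up) if pd.notna(up) and up is not None else profile.utr_window[0],
            int(down) if pd.notna(down) and down is not None else profile.utr_window[1],
        )
        genes[row.gene_id] = GeneModel(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            stop_codon_end=int(row.stop_codon_end),
            utr_window=window,
        )
    return genes


def write_annotation(genes: dict[str, GeneModel],
                     path: str | os.PathLike) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "stop_codon_end": g.stop_codon_end,
            "upstream_extent": g.utr_window[0],
            "downstream_extent": g.utr_window[1],
        }
        for g in genes.values()
    ]
    pd.DataFrame(rows, columns=_ANN_COLS + ["upstream_extent",
                                            "downstream_extent"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED-like mapped endpoints (chrom, pos, strand, t_count[, read_id])

_BED_COLS = ["chrom", "pos", "strand", "t_count"]


def load_endpoints_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"endpoint table {path} missing columns {missing}")
    return df


def write_endpoints_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stranded single-base 3'-end coverage (bedGraph pair, one file per strand)


class EndCoverage:
    """Point-queryable per-base 3'-end counts, keyed by (chrom, strand)."""

    def __init__(self):
        self._data: dict[tuple[str, str], dict[int, float]] = defaultdict(dict)

    def add(self, chrom: str, pos: int, strand: str, count: float = 1) -> None:
        if count < 0:
            raise ValueError(f"negative count {count} at {chrom}:{pos}")
        if strand not in "+-":
            raise ValueError(f"invalid strand {strand!r}")
        key = (chrom, strand)
        self._data[key][pos] = self._data[key].get(pos, 0) + count

    def query(self, chrom: str, pos: int, strand: str) -> float:
        return self._data.get((chrom, strand), {}).get(pos, 0)

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total counts at positions in [start, end] inclusive."""
        track = self._data.get((chrom, strand), {})
        if not track:
            return 0.0
        if end - start > len(track):
            return sum(c for p, c in track.items() if start <= p <= end)
        return sum(track.get(p, 0) for p in range(start, end + 1))

    def total(self) -> float:
        return sum(sum(t.values()) for t in self._data.values())

    def items(self):
        for (chrom, strand), track in self._data.items():
            for pos, count in track.items():
                yield chrom, pos, strand, count

    @classmethod
    def from_bedgraph_pair(cls, plus_path: str | os.PathLike | None = None,
                           minus_path: str | os.PathLike | None = None
                           ) -> "EndCoverage":
        cov = cls()
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            if path is None:
                continue
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["chrom", "start", "end", "count"])
            if (df["count"] < 0).any():
                raise ValueError(f"negative counts in bedGraph {path}")
            for row in df.itertuples(index=False):
                for pos in range(int(row.start), int(row.end)):
                    cov.add(row.chrom, pos, strand, row.count)
        return cov

    def to_bedgraph_pair(self, plus_path: str | os.PathLike,
                         minus_path: str | os.PathLike) -> None:
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            rows = []
            for (chrom, s), track in sorted(self._data.items()):
                if s != strand:
                    continue
                for pos in sorted(track):
                    if track[pos] != 0:
                        rows.append((chrom, pos, pos + 1, track[pos]))
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
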