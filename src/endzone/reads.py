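"""3' READS computational preprocessing.

Reads carry 4 random nt, then the reverse-complemented poly(A) tail as a
leading T-run, then sequence matching the template. Preprocessing strips the
random 4-mer, requires the first non-random base to be a T (else the fragment
did not end in A and is discarded), records the T count, and truncates the
remainder before mapping. After mapping, reads whose leading-T count is fully
explained by a genomic A-run immediately 3' of the mapped end are discarded
as internal-priming artifacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SpeciesProfile, YEAST
from .genome import GeneModel, GenomeSequence, reverse_complement


@dataclass(frozen=True)
class TaggedRead:
    read_id: str
    t_count: int
    trimmed_seq: str


def parse_fastq(path) -> list[tuple[str, str]]:
    """Minimal FASTQ reader: (read_id, sequence) pairs."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header.strip()[1:].split()[0], seq))
    return out


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def preprocess_reads(reads: list[tuple[str, str]],
                     profile: SpeciesProfile = YEAST
                     ) -> tuple[list[TaggedRead], Counter]:
    """Trim the random 4-mer, enforce the leading-T rule, count and strip the
    T-run, truncate the remainder to the profile's mapping length.

    Returns the surviving TaggedReads and a Counter of drop reasons
    (too_short, first_base_not_T, all_T).
    """
    kept: list[TaggedRead] = []
    drops: Counter = Counter()
    trunc = profile.read_truncate_len
    for rid, seq in reads:
        seq = seq.upper()
        if len(seq) < 6:
            drops["too_short"] += 1
            continue
        body = seq[4:]
        if body[0] != "T":
            drops["first_base_not_T"] += 1
            continue
        t = len(body) - len(body.lstrip("T"))
        rest = body[t:]
        if not rest:
            drops["all_T"] += 1
            continue
        kept.append(TaggedRead(read_id=rid, t_count=t,
                               trimmed_seq=rest[:trunc]))
    return kept, drops


def naive_align(tagged: list[TaggedRead], genome: GenomeSequence
                ) -> pd.DataFrame:
    """Exact-match aligner for fixture-scale end-to-end tests.

    The trimmed read is the reverse complement of the sense-strand sequence
    ending at the mRNA 3' end, so a unique match of its reverse complement on
    a chromosome's forward strand implies a plus-strand transcript whose 3'
    end is the match's last base; a unique forward match implies a
    minus-strand transcript ending at the match's first base. Ambiguous or
    unmatched reads are dropped.
    """
    rows = []
    for read in tagged:
        query_rc = reverse_complement(read.trimmed_seq)  # sense-strand form
        hits = []
        for chrom in genome.chromosomes:
            seq = genome.sequence(chrom)
            start = seq.find(query_rc)
            while start != -1:
                hits.append((chrom, start + len(query_rc) - 1, "+"))
                start = seq.find(query_rc, start + 1)
            start = seq.find(read.trimmed_seq)
            while start != -1:
                hits.append((chrom, start, "-"))
                start = seq.find(read.trimmed_seq, start + 1)
        if len(hits) == 1:
            chrom, pos, strand = hits[0]
            rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                         "t_count": read.t_count, "read_id": read.read_id})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "t_count",
                                       "read_id"])


def genomic_a_run(genome: GenomeSequence, chrom: str, pos: int, strand: str,
                  limit: int) -> int:
    """Length of the uninterrupted sense-strand A-run starting immediately 3'
    of ``pos``, scanning at most ``limit`` bases."""
    n = genome.length(chrom)
    run = 0
    if strand == "+":
        p = pos + 1
        while p < n and run < limit and genome.sequence(chrom)[p] == "A":
            run += 1
            p += 1
    else:
        p = pos - 1
        # sense-strand A on the minus strand is a T on the forward strand
        while p >= 0 and run < limit and genome.sequence(chrom)[p] == "T":
            run += 1
            p -= 1
    return run


def filter_internal_priming(mapped: pd.DataFrame, genome: GenomeSequence
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard reads whose genomic downstream A-run can account for all of
    their leading Ts: retained iff A-run length < t_count.

    Returns (retained, discarded) endpoint tables.
    """
    keep_mask = []
    for row in mapped.itertuples(index=False):
        if not (0 <= row.pos < genome.length(row.chrom)):
            raise ValueError(f"endpoint {row.chrom}:{row.pos} outside genome")
        if row.t_count < 1:
            raise ValueError("t_count must be >= 1 for mapped poly(A) reads")
        run = genomic_a_run(genome, row.chrom, int(row.pos), row.strand,
                            limit=int(row.t_count))
        keep_mask.append(run < row.t_count)
    keep_mask = np.array(keep_mask, dtype=bool) if len(keep_mask) else \
        np.zeros(0, dtype=bool)
    return mapped[keep_mask].copy(), mapped[~keep_mask].copy()


def consolidate_and_scale(replicates: list[pd.DataFrame],
                          target: float = 25_000_000.0) -> pd.DataFrame:
    """Sum replicate endpoint counts and scale the combined total to
    ``target`` poly(A) reads; proportions are preserved exactly."""
    if not replicates:
        raise ValueError("need at least one replicate")
    if target <= 0:
        raise ValueError("target must be positive")
    frames = []
    for df in replicates:
        need = {"chrom", "pos", "strand"} - set(df.columns)
        if need:
            raise ValueError(f"replicate missing columns {sorted(need)}")
        d = df.copy()
        if "count" not in d.columns:
            d["count"] = 1.0
        frames.append(d[["chrom", "pos", "strand", "count"]])
    combined = (pd.concat(frames, ignore_index=True)
                .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
                .sum())
    total = combined["count"].sum()
    if total == 0:
        raise ValueError("all-zero input; cannot scale")
    combined["count"] *= target / total
    return combined


def assign_to_genes(endpoints: pd.DataFrame, genes: dict[str, GeneModel],
                    profile: SpeciesProfile = YEAST
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Assign strand-matched endpoints falling inside gene windows to genes,
    in transcript offsets.

    Endpoints inside two genes' windows go to the gene whose stop codon is
    nearest upstream; ambiguities are reported in the returned log. Under a
    mitochondria-excluding profile, endpoints on mitochondrial contigs are
    dropped.
    """
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes.values():
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    log: list[str] = []
    rows = []
    mito = set(profile.mito_names) if profile.exclude_mitochondrial else set()
    for row in endpoints.itertuples(index=False):
        if row.chrom in mito:
            continue
        cands = []
        for g in by_loc.get((row.chrom, row.strand), []):
            off = g.genomic_to_offset(int(row.pos))
            if g.contains_offset(off):
                cands.append((g, off))
        if not cands:
            continue
        if len(cands) > 1:
            # nearest upstream stop codon = smallest non-negative offset,
            # falling back to the least-negative one
            cands.sort(key=lambda t: (t[1] < 1, abs(t[1])))
            log.append(
                f"{row.chrom}:{row.pos}{row.strand} in windows of "
                f"{[g.gene_id for g, _ in cands]}; assigned to "
                f"{cands[0][0].gene_id}")
        g, off = cands[0]
        count = getattr(row, "count", 1.0)
        rows.append({"gene_id": g.gene_id, "offset": off, "count": count})
    df = pd.DataFrame(rows, columns=["gene_id", "offset", "count"])
    if not df.empty:
        df = df.groupby(["gene_id", "offset"], as_index=False)["count"].sum()
    return df, log
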