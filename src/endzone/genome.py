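"""Genome sequences and gene models in transcript coordinates.

Genomic coordinates are 0-based half-open throughout. Transcript offsets are
1-based nucleotides downstream of the last base of the stop codon on the sense
strand: offset 1 is the first 3'UTR base, offset 0 the stop codon's final base,
and negative offsets reach upstream into the coding region.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory random-access genome: per-chromosome nucleotide strings.

    ``fetch`` with ``strand='-'`` returns the reverse complement; requests
    outside a contig raise rather than truncate.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"window [{start}, {end}) outside {chrom} (length {n})"
            )
        if strand not in "+-":
            raise ValueError(f"invalid strand {strand!r}")
        seq = self._seqs[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its stop codon with a 3'UTR analysis window.

    ``stop_codon_end`` is the genomic coordinate (0-based) of the last stop
    codon base on the sense strand.  ``utr_window`` is
    ``(upstream_extent, downstream_extent)`` in nt relative to that anchor;
    endpoints with transcript offset in ``[1 - upstream_extent,
    downstream_extent]`` belong to the gene.
    """

    gene_id: str
    chrom: str
    strand: str
    stop_codon_end: int
    utr_window: tuple[int, int] = (0, 1500)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.utr_window[1] <= 0:
            raise ValueError(f"{self.gene_id}: downstream extent must be > 0")

    def offset_to_genomic(self, offset: int) -> int:
        if self.strand == "+":
            return self.stop_codon_end + offset
        return self.stop_codon_end - offset

    def genomic_to_offset(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.stop_codon_end
        return self.stop_codon_end - pos

    def contains_offset(self, offset: int) -> bool:
        up, down = self.utr_window
        return (1 - up) <= offset <= down

    def utr_offsets(self) -> range:
        """Transcript offsets of the 3'UTR proper (1..downstream extent)."""
        return range(1, self.utr_window[1] + 1)

    def fetch_offsets(self, genome: GenomeSequence, start_offset: int,
                      end_offset: int) -> str:
        """Sense-strand sequence spanning transcript offsets
        ``start_offset..end_offset`` inclusive."""
        if end_offset < start_offset:
            raise ValueError("end_offset < start_offset")
        a = self.offset_to_genomic(start_offset)
        b = self.offset_to_genomic(end_offset)
        lo, hi = (a, b) if self.strand == "+" else (b, a)
        return genome.fetch(self.chrom, lo, hi + 1, self.strand)

    def base_at_offset(self, genome: GenomeSequence, offset: int) -> str:
        g = self.offset_to_genomic(offset)
        return genome.fetch(self.chrom, g, g + 1, self.strand)
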