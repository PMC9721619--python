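"""Run configuration and species profiles.

The two profiles bundle every printed analysis parameter for the yeast and
human arms so they cannot be silently mixed: the 4-nt cluster gap, the
major-isoform rules, gene read floors, the 25-million-read scale target, the
Pearson-R quality gates, and the spacing-bin ranges.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    max_intra_cluster_gap: int = 4
    major_isoform_fraction: float = 0.05
    major_fraction_strict: bool = False   # True → strictly >5% of max
    low_depth_max_isoform: int | None = None  # human: max-isoform count below
    low_depth_min_reads: int = 5              # which the absolute rule applies
    gene_min_reads: float = 1000.0
    scale_target: float = 25_000_000.0
    slope_R_threshold: float = 0.7
    gc_quality_R_threshold: float = 0.5
    max_within_spacing: int = 15
    utr_window: tuple[int, int] = (0, 1500)
    read_truncate_len: int = 17
    exclude_mitochondrial: bool = False
    mito_names: tuple[str, ...] = ("chrM", "chrMT", "MT", "Mito")


YEAST = SpeciesProfile(name="yeast")

HUMAN = SpeciesProfile(
    name="human",
    major_fraction_strict=True,
    low_depth_max_isoform=100,
    gene_min_reads=0.0,
    slope_R_threshold=0.6,
    max_within_spacing=14,
    utr_window=(1000, 5000),
    read_truncate_len=77,
    exclude_mitochondrial=True,
)

PROFILES = {"yeast": YEAST, "human": HUMAN}


@dataclass(frozen=True)
class RunConfig:
    """All knobs for one analysis run; profile supplies the defaults."""

    profile: SpeciesProfile = YEAST
    n_shuffles: int = 100_000
    rng_seed: int = 0
    fdr_alpha: float = 0.05

    def __post_init__(self):
        p = self.profile
        for name, v in (
            ("max_intra_cluster_gap", p.max_intra_cluster_gap),
            ("major_isoform_fraction", p.major_isoform_fraction),
            ("scale_target", p.scale_target),
            ("slope_R_threshold", p.slope_R_threshold),
            ("gc_quality_R_threshold", p.gc_quality_R_threshold),
            ("n_shuffles", self.n_shuffles),
            ("fdr_alpha", self.fdr_alpha),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if p.gene_min_reads < 0:
            raise ValueError("gene_min_reads must be >= 0")


def get_profile(name: str) -> SpeciesProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown species profile {name!r}; choose from {sorted(PROFILES)}"
        ) from None
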