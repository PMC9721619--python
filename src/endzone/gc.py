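"""Sequence composition around isoform clusters vs cluster slopes.

Sliding 10-nt windows upstream (−100..−1 of the cluster's 5'-most isoform) or
downstream (+1..+100 of its 3'-most isoform) are correlated with cluster
slopes across clusters; P values are Benjamini–Hochberg corrected across
window positions within a region. A quintile analysis summarises the percent
change in GC content at +13..+30 relative to a 3'UTR background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, GenomeSequence
from .shift import SlopeRecord

GC_REGION = (13, 30)  # transcript offsets downstream of the 3'-most isoform


def window_gc(genome: GenomeSequence, gene: GeneModel, anchor_offset: int,
              window_start: int, width: int = 10) -> float:
    """GC fraction of the sense-strand window spanning transcript offsets
    anchor+window_start .. anchor+window_start+width-1."""
    a = anchor_offset + window_start
    seq = gene.fetch_offsets(genome, a, a + width - 1)
    return sum(b in "GC" for b in seq) / width


def _gated(records: list[SlopeRecord], r_gate: float) -> list[SlopeRecord]:
    return [r for r in records if r.gated and abs(r.pearson_r) > r_gate]


def slope_gc_scan(records: list[SlopeRecord], genes: dict[str, GeneModel],
                  genome: GenomeSequence, region: str = "downstream",
                  r_gate: float = 0.5, width: int = 10,
                  span: int = 100, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of window GC content with cluster slope at each
    sliding-window start within the region, with BH FDR over positions.

    ``region='downstream'`` anchors windows at the cluster's 3'-most isoform
    (starts +1..+(span-width+1)); ``'upstream'`` anchors at the 5'-most
    isoform (starts −span..−width). Clusters whose window leaves the contig
    are excluded at that position only.
    """
    recs = _gated(records, r_gate)
    if len(recs) < 3:
        raise ValueError(f"need >=3 clusters after |R|>{r_gate} gating, "
                         f"got {len(recs)}")
    if region == "downstream":
        starts = range(1, span - width + 2)
    elif region == "upstream":
        starts = range(-span, -width + 1)
    else:
        raise ValueError("region must be 'downstream' or 'upstream'")
    rows = []
    for s in starts:
        gcs, slopes = [], []
        for rec in recs:
            gene = genes[rec.gene_id]
            anchor = rec.three_prime_most if region == "downstream" \
                else rec.five_prime_most
            try:
                gcs.append(window_gc(genome, gene, anchor, s, width))
            except ValueError:
                continue
            slopes.append(rec.slope)
        if len(gcs) < 3 or np.ptp(gcs) == 0:
            continue
        r, p = stats.pearsonr(gcs, slopes)
        rows.append({"window_start": s, "n_clusters": len(gcs),
                     "pearson_r": float(r), "p_value": float(p)})
    df = pd.DataFrame(rows, columns=["window_start", "n_clusters",
                                     "pearson_r", "p_value"])
    if df.empty:
        df["fdr_q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    rej, q, _, _ = multipletests(df["p_value"], alpha=fdr_alpha, method="fdr_bh")
    df["fdr_q"] = q
    df["significant"] = rej
    return df


def utr_background_gc(genes: dict[str, GeneModel], genome: GenomeSequence,
                      width: int = GC_REGION[1] - GC_REGION[0] + 1) -> float:
    """Median GC fraction over all width-nt windows fully inside the
    analysed genes' 3'UTRs — the background for the quintile analysis."""
    vals = []
    for gene in genes.values():
        down = gene.utr_window[1]
        try:
            seq = gene.fetch_offsets(genome, 1, down)
        except ValueError:
            continue
        gc = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (gc == ord("G")) | (gc == ord("C"))
        if len(seq) < width:
            continue
        csum = np.concatenate(([0], np.cumsum(is_gc)))
        vals.extend(((csum[width:] - csum[:-width]) / width).tolist())
    if not vals:
        raise ValueError("no 3'UTR windows available for background GC")
    return float(np.median(vals))


def quintile_gc_change(records: list[SlopeRecord],
                       genes: dict[str, GeneModel], genome: GenomeSequence,
                       r_gate: float = 0.5,
                       gc_region: tuple[int, int] = GC_REGION,
                       background: float | None = None) -> pd.DataFrame:
    """Split gated cluster slopes into quintiles (ascending; stable on ties)
    and report each quintile's mean percent change in GC content at
    +13..+30 downstream of the cluster vs the 3'UTR background."""
    recs = _gated(records, r_gate)
    if len(recs) < 5:
        raise ValueError(f"need >=5 gated clusters, got {len(recs)}")
    lo, hi = gc_region
    width = hi - lo + 1
    if background is None:
        background = utr_background_gc(genes, genome, width=width)
    if background == 0:
        raise ValueError("background GC is zero; degenerate genome")
    usable = []
    for rec in recs:
        gene = genes[rec.gene_id]
        try:
            gc = window_gc(genome, gene, rec.three_prime_most, lo, width)
        except ValueError:
            continue
        usable.append((rec.slope, 100.0 * (gc - background) / background))
    usable.sort(key=lambda t: t[0])  # stable: ties keep insertion order
    chunks = np.array_split(np.arange(len(usable)), 5)
    rows = []
    for qi, idx in enumerate(chunks, start=1):
        slopes = [usable[i][0] for i in idx]
        changes = [usable[i][1] for i in idx]
        rows.append({
            "quintile": qi, "n_clusters": len(idx),
            "mean_pct_gc_change": float(np.mean(changes)),
            "median_slope": float(np.median(slopes)),
        })
    return pd.DataFrame(rows, columns=["quintile", "n_clusters",
                                       "mean_pct_gc_change", "median_slope"])
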