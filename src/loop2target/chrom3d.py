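"""Loop-based SNP-to-gene mapping, hub-enhancer calling, and interval-overlap
enrichment statistics.

A chromatin loop joins two fixed-resolution anchor bins (5 kb by default);
a GWAS SNP is mapped to a gene when the SNP lies in one anchor of a loop
whose other anchor intersects the gene's promoter (TSS +/- 2 kb).  Hub
enhancers are anchor bins whose number of distinct loop partners reaches
the 90th percentile of the anchor-degree distribution.  All interval
arithmetic is 0-based half-open: touching intervals never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Loop
from .util import GenomicInterval, merge_intervals

AnchorBin = tuple[str, int]  # (chrom, bin start)


def filter_loops(loops: list[Loop], fdr: float = 1e-6) -> list[Loop]:
    """Retain loops with qvalue strictly below the FDR cut (canonical anchors)."""
    return [lp for lp in loops if lp.qvalue < fdr]


def promoters(genes: pd.DataFrame, flank: int = 2000) -> list[tuple[str, GenomicInterval]]:
    """Promoter intervals [TSS - flank, TSS + flank), clipped at zero.

    The annotation already stores the strand-resolved TSS (1-based); the
    interval is symmetric so strand affects only the TSS choice upstream.
    """
    out = []
    for rec in genes.itertuples(index=False):
        tss0 = int(rec.tss) - 1  # 1-based TSS -> 0-based coordinate
        out.append(
            (rec.gene_id, GenomicInterval(rec.chrom, max(0, tss0 - flank), tss0 + flank))
        )
    return out


@dataclass
class Snp3dMap:
    """SNP-enhancer-promoter loop pairs and their summary statistics."""

    pairs: list[tuple[str, str, Loop, float]]  # (snp_id, gene_id, loop, distance_bp)
    genes: set = field(default_factory=set)
    loops_per_promoter_mean: float = float("nan")
    mean_distance_bp: float = float("nan")

    COLUMNS = (
        "snp_id", "gene_id", "chrom", "anchor1_start", "anchor2_start",
        "qvalue", "distance_bp",
    )

    def as_frame(self) -> pd.DataFrame:
        if not self.pairs:
            return pd.DataFrame(columns=list(self.COLUMNS))
        return pd.DataFrame(
            [
                {
                    "snp_id": s,
                    "gene_id": g,
                    "chrom": lp.anchor1.chrom,
                    "anchor1_start": lp.anchor1.start,
                    "anchor2_start": lp.anchor2.start,
                    "qvalue": lp.qvalue,
                    "distance_bp": d,
                }
                for s, g, lp, d in self.pairs
            ]
        )


def map_snps_3d(
    ind_sig_snps: list[tuple[str, str, int]],
    loops: list[Loop],
    promoter_list: list[tuple[str, GenomicInterval]],
) -> Snp3dMap:
    """Map SNPs to genes through loops.

    ``ind_sig_snps`` is (snp_id, chrom, pos 1-based).  A (snp, gene) pair is
    emitted once per loop where the SNP position lies inside one anchor and
    the gene's promoter intersects the other anchor; a SNP sitting in the
    promoter-side anchor only does not map (the SNP must tag the distal
    anchor for that promoter).  Distance is between anchor midpoints.
    Duplicate (snp, gene) pairs across loops are retained in ``pairs`` and
    deduplicated in ``genes``.
    """
    pairs: list[tuple[str, str, Loop, float]] = []
    for lp in loops:
        dist = abs(lp.anchor1.midpoint - lp.anchor2.midpoint)
        emitted: set[tuple[str, str]] = set()  # one pair per (snp, gene, loop)
        for anchor_snp, anchor_prom in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            snps_in = [
                sid
                for sid, chrom, pos in ind_sig_snps
                if anchor_snp.contains_point(chrom, pos - 1)
            ]
            if not snps_in:
                continue
            genes_in = [g for g, iv in promoter_list if iv.overlaps(anchor_prom)]
            for sid in snps_in:
                for g in genes_in:
                    if (sid, g) not in emitted:
                        emitted.add((sid, g))
                        pairs.append((sid, g, lp, dist))
    genes = {g for _, g, _, _ in pairs}
    if pairs:
        per_prom = pd.Series([g for _, g, _, _ in pairs]).value_counts()
        lpp = float(per_prom.mean())
        mdist = float(np.mean([d for _, _, _, d in pairs]))
    else:
        lpp, mdist = float("nan"), float("nan")
    return Snp3dMap(
        pairs=pairs, genes=genes, loops_per_promoter_mean=lpp, mean_distance_bp=mdist
    )


def anchor_degrees(loops: list[Loop]) -> dict[AnchorBin, int]:
    """Distinct-partner degree per anchor bin (duplicate edges collapsed)."""
    edges = set()
    for lp in loops:
        a = (lp.anchor1.chrom, lp.anchor1.start)
        b = (lp.anchor2.chrom, lp.anchor2.start)
        if a != b:
            edges.add(tuple(sorted((a, b))))
    deg: dict[AnchorBin, int] = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg


def _nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: smallest value with >= percentile% at or below."""
    srt = np.sort(values)
    rank = int(np.ceil(percentile / 100.0 * len(srt)))
    rank = min(max(rank, 1), len(srt))
    return float(srt[rank - 1])


def hub_enhancers(loops: list[Loop], percentile: float = 90) -> set[AnchorBin]:
    """Anchor bins whose distinct-partner degree is >= the empirical percentile.

    Ties at the threshold degree are included (>=, as conventionally
    printed); fewer than 10 anchor nodes make the percentile unstable and
    raise an error.
    """
    deg = anchor_degrees(loops)
    if len(deg) < 10:
        raise ValueError("hub calling requires >= 10 anchor nodes")
    thr = _nearest_rank_percentile(np.array(list(deg.values())), percentile)
    return {node for node, d in deg.items() if d >= thr}


def projection_overlap_test(
    queries: list[GenomicInterval] | list[tuple[str, int]],
    reference: list[GenomicInterval],
    genome_length: int,
) -> tuple[float, float]:
    """Projection test of query/reference overlap (binomial).

    Each query is reduced to its midpoint (a bare (chrom, pos0) point is
    also accepted); the hit probability is the merged reference coverage
    divided by the genome length and the number of midpoints falling in
    the reference is tested against Binomial(n, p), two-sided exact.
    Returns (fold = observed / expected, p-value).
    """
    merged = merge_intervals(reference)
    cov = sum(len(iv) for iv in merged)
    if cov == 0:
        raise ValueError("reference has zero coverage")
    if genome_length < cov:
        raise ValueError("genome_length smaller than reference coverage")
    p_hit = cov / genome_length
    points = []
    for q in queries:
        if isinstance(q, GenomicInterval):
            points.append((q.chrom, int(q.midpoint)))
        else:
            points.append((q[0], int(q[1])))
    n = len(points)
    obs = sum(
        1
        for chrom, pos in points
        if any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in merged)
    )
    fold = obs / (n * p_hit)
    pval = stats.binomtest(obs, n, p_hit, alternative="two-sided").pvalue
    return float(fold), float(pval)


def snp_hub_enrichment(
    ind_sig_snps: list[tuple[str, str, int]],
    hub_bins: set[AnchorBin],
    all_anchor_bins: set[AnchorBin],
    bin_size: int = 5000,
) -> tuple[float, float]:
    """Observed/expected enrichment of SNPs in hub anchors among anchor SNPs.

    Among SNPs falling in any anchor bin, the expected hub fraction is the
    hub share of anchor coverage; the observed hub-SNP count is tested with
    an exact upper-tail binomial.
    """
    if not hub_bins <= all_anchor_bins:
        raise ValueError("hub_bins must be a subset of all_anchor_bins")
    p_hub = len(hub_bins) * bin_size / (len(all_anchor_bins) * bin_size)
    in_anchor = 0
    in_hub = 0
    for _, chrom, pos in ind_sig_snps:
        b = (chrom, ((pos - 1) // bin_size) * bin_size)
        if b in all_anchor_bins:
            in_anchor += 1
            if b in hub_bins:
                in_hub += 1
    if in_anchor == 0:
        raise ValueError("no SNPs fall in anchor bins")
    fold = (in_hub / in_anchor) / p_hub
    pval = stats.binomtest(in_hub, in_anchor, p_hub, alternative="greater").pvalue
    return float(fold), float(pval)


def anchor_intervals(loops: list[Loop]) -> list[GenomicInterval]:
    """All anchor bins of a loop list as (merged-ready) intervals."""
    seen = set()
    out = []
    for lp in loops:
        for a in (lp.anchor1, lp.anchor2):
            key = (a.chrom, a.start, a.end)
            if key not in seen:
                seen.add(key)
                out.append(a)
    return out
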