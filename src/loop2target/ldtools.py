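"""LD computation and FUMA-style definition of independent significant SNPs,
lead SNPs, and merged genomic risk loci from GWAS summary statistics.

Clumping is the greedy scheme used by FUMA/PLINK: significant,
MAF-passing variants are ranked by ascending p-value and accepted iff
their LD r-squared with every previously accepted variant stays below the
threshold.  All thresholds are strict (<) except the MAF floor (>=),
matching the conventional printed cutoffs (P < 5e-8, r2 < 0.6 for
independent significant SNPs, r2 < 0.1 for lead SNPs, MAF >= 0.01; loci
closer than 250 kb are merged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypePanel

logger = logging.getLogger("loop2target.ldtools")


@dataclass
class ClumpResult:
    """Independent significant SNPs, lead SNPs, and merged genomic risk loci."""

    ind_sig: list[str]
    lead: list[str]
    loci: list[tuple[str, int, int, list[str]]]  # (chrom, start, end, members)

    def __post_init__(self) -> None:
        if not set(self.lead) <= set(self.ind_sig):
            raise ValueError("every lead SNP must be an independent significant SNP")


def ld_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two dosage columns."""
    if snp_a == snp_b:
        panel.index_of(snp_a)
        return 1.0
    ga = panel.dosages[:, panel.index_of(snp_a)].astype(float)
    gb = panel.dosages[:, panel.index_of(snp_b)].astype(float)
    va, vb = ga.var(), gb.var()
    if va == 0 or vb == 0:
        raise ValueError("r2 undefined for a monomorphic variant")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def _maf(panel: GenotypePanel, idx: int) -> float:
    af = panel.dosages[:, idx].mean() / 2.0
    return min(af, 1.0 - af)


def _greedy_prune(
    ordered_ids: list[str], panel: GenotypePanel, r2_thresh: float
) -> list[str]:
    """Accept each variant iff r2 with every previously accepted one < r2_thresh."""
    accepted: list[str] = []
    cols: list[np.ndarray] = []
    for sid in ordered_ids:
        g = panel.dosages[:, panel.index_of(sid)].astype(float)
        if g.var() == 0:
            continue
        ok = True
        for other in cols:
            r = np.corrcoef(g, other)[0, 1]
            if r * r >= r2_thresh:
                ok = False
                break
        if ok:
            accepted.append(sid)
            cols.append(g)
    return accepted


def _p_sorted(sumstats: pd.DataFrame) -> pd.DataFrame:
    # deterministic: ties in P broken by (chrom, pos, snp_id)
    return sumstats.sort_values(
        ["pvalue", "chrom", "pos", "snp_id"], kind="mergesort"
    )


def clump_ind_sig(
    sumstats: pd.DataFrame,
    panel: GenotypePanel,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.6,
    maf_min: float = 0.01,
) -> list[str]:
    """Greedy clumping to independent significant SNPs.

    MAF is computed from the panel (the LD reference), not from the
    summary-statistic EAF column; variants absent from the panel are
    dropped with a logged count.
    """
    in_panel = set(panel.variants["snp_id"])
    present = sumstats[sumstats["snp_id"].isin(in_panel)]
    n_dropped = len(sumstats) - len(present)
    if n_dropped:
        logger.info("clump_ind_sig: dropped %d variants absent from panel", n_dropped)
    sig = present[present["pvalue"] < p_thresh]
    if sig.empty:
        return []
    keep = [
        sid
        for sid in _p_sorted(sig)["snp_id"]
        if _maf(panel, panel.index_of(sid)) >= maf_min
    ]
    return _greedy_prune(keep, panel, r2_thresh)


def lead_snps(
    ind_sig: list[str], panel: GenotypePanel, r2_thresh: float = 0.1
) -> list[str]:
    """Lead SNPs: the greedy scheme re-applied to ind_sig at r2 < 0.1.

    ``ind_sig`` must be in ascending-p order, which is how
    :func:`clump_ind_sig` returns it.
    """
    if not ind_sig:
        raise ValueError("ind_sig must be non-empty")
    return _greedy_prune(list(ind_sig), panel, r2_thresh)


def merge_loci(
    ind_sig_positions: list[tuple[str, str, int]], gap: int = 250_000
) -> list[tuple[str, int, int, list[str]]]:
    """Single-linkage merge of per-SNP loci whose boundary SNPs are < gap apart.

    ``ind_sig_positions`` is a list of (snp_id, chrom, pos 1-based); the
    returned loci are (chrom, start, end, member snp_ids) with span equal
    to [min pos, max pos] of the members.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for sid, chrom, pos in ind_sig_positions:
        by_chrom.setdefault(chrom, []).append((int(pos), sid))
    loci = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        cur = [items[0]]
        for pos, sid in items[1:]:
            if pos - cur[-1][0] < gap:
                cur.append((pos, sid))
            else:
                loci.append((chrom, cur[0][0], cur[-1][0], [s for _, s in cur]))
                cur = [(pos, sid)]
        loci.append((chrom, cur[0][0], cur[-1][0], [s for _, s in cur]))
    return loci


def clump(
    sumstats: pd.DataFrame,
    panel: GenotypePanel,
    p_thresh: float = 5e-8,
    r2_ind: float = 0.6,
    r2_lead: float = 0.1,
    maf_min: float = 0.01,
    merge_gap: int = 250_000,
) -> ClumpResult:
    """Full locus definition: independent significant SNPs, lead SNPs, merged loci."""
    ind_sig = clump_ind_sig(sumstats, panel, p_thresh, r2_ind, maf_min)
    if not ind_sig:
        return ClumpResult(ind_sig=[], lead=[], loci=[])
    lead = lead_snps(ind_sig, panel, r2_lead)
    pos_map = sumstats.set_index("snp_id")
    positions = [
        (s, str(pos_map.loc[s, "chrom"]), int(pos_map.loc[s, "pos"])) for s in ind_sig
    ]
    loci = merge_loci(positions, merge_gap)
    return ClumpResult(ind_sig=ind_sig, lead=lead, loci=loci)
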