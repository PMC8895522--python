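"""cis-eQTL SNP-to-gene mapping of independent significant GWAS SNPs and
3D/eQTL gene-set overlap enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .util import bh_adjust


@dataclass
class SnpEqtlPair:
    snp_id: str
    gene_id: str
    eqtl_beta: float
    eqtl_p: float
    bh_fdr: float


def map_snp_eqtl(
    ind_sig: list[str],
    eqtl_sumstats: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 500_000,
    fdr: float = 0.05,
) -> list[SnpEqtlPair]:
    """Map independent significant SNPs to genes in cis (TSS +/- window).

    eQTL records are restricted to SNPs in ``ind_sig`` with |pos - TSS| <=
    window; Benjamini-Hochberg adjustment is applied jointly across all
    retained SNP-gene pairs (not per gene), and pairs with adjusted p <
    ``fdr`` are returned.
    """
    tss = genes.set_index("gene_id")["tss"]
    sub = eqtl_sumstats[eqtl_sumstats["snp_id"].isin(set(ind_sig))].copy()
    sub = sub[sub["gene_id"].isin(tss.index)]
    dist = (sub["pos"].to_numpy() - tss.loc[sub["gene_id"]].to_numpy())
    sub = sub[abs(dist) <= window]
    if sub.empty:
        return []
    adj = bh_adjust(sub["pvalue"].to_numpy())
    sub = sub.assign(bh_fdr=adj)
    keep = sub[sub["bh_fdr"] < fdr]
    return [
        SnpEqtlPair(
            snp_id=r.snp_id,
            gene_id=r.gene_id,
            eqtl_beta=float(r.beta),
            eqtl_p=float(r.pvalue),
            bh_fdr=float(r.bh_fdr),
        )
        for r in keep.itertuples(index=False)
    ]


def overlap_enrichment_3d_eqtl(
    genes_3d: set, genes_eqtl: set, background_n: int
) -> tuple[float, float]:
    """Enrichment of eQTL genes among loop-mapped genes (exact binomial).

    Expected hit probability is |genes_eqtl| / background_n; the overlap
    count among |genes_3d| trials is tested upper-tail.  The background
    gene count must be supplied explicitly (e.g. the number of annotated
    protein-coding genes).
    """
    if background_n <= 0:
        raise ValueError("background_n must be positive")
    if background_n < len(genes_3d | genes_eqtl):
        raise ValueError("background_n smaller than the union of gene sets")
    n = len(genes_3d)
    if n == 0:
        raise ValueError("genes_3d is empty")
    p_hit = len(genes_eqtl) / background_n
    obs = len(genes_3d & genes_eqtl)
    expected = n * p_hit
    fold = obs / expected if expected > 0 else float("nan")
    pval = stats.binomtest(obs, n, p_hit, alternative="greater").pvalue if p_hit > 0 else 1.0
    return float(fold), float(pval)
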