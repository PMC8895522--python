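"""Two-trait Bayesian colocalization between a gene's cis-eQTL signal and a
GWAS signal via Wakefield approximate Bayes factors.

The classical single-causal-variant enumeration over five hypotheses is
used: H0 no association; H1 eQTL only; H2 GWAS only; H3 two distinct
causal variants; H4 one shared causal variant.  Per-SNP log-ABFs are
combined by log-sum-exp, priors default to the standard coloc values
(p1 = p2 = 1e-4, p12 = 1e-5), and a region is declared colocalized when
PP(H4) > 0.8.  Effect alleles of the two sources are harmonized before
intersection (sign flip on swapped alleles; strand-ambiguous A/T-C/G
SNPs dropped when the allele frequency is in [0.4, 0.6]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("loop2target.colocal")

HYPOTHESES = ["H0", "H1", "H2", "H3", "H4"]
_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def wakefield_abf(beta: float, se: float, w_sd: float) -> float:
    """Natural-log Wakefield approximate Bayes factor for one association.

    With z = beta/se and r = W^2 / (W^2 + se^2),
    log ABF = 0.5 * [log(1 - r) + z^2 * r]; W is the prior SD of the true
    effect under the alternative.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if w_sd <= 0:
        raise ValueError("w_sd must be positive")
    z = beta / se
    r = w_sd**2 / (w_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + z * z * r)


def harmonize(
    gwas: pd.DataFrame, eqtl: pd.DataFrame, drop_palindromic_band: tuple[float, float] = (0.4, 0.6)
) -> pd.DataFrame:
    """Intersect two summary tables on snp_id with allele harmonization.

    Returns a frame with columns beta_gwas/se_gwas/beta_eqtl/se_eqtl; the
    eQTL effect is sign-flipped when its effect/other alleles are swapped
    relative to the GWAS, and rows with irreconcilable alleles or
    ambiguous palindromes at intermediate frequency are dropped.
    """
    g = gwas.drop_duplicates(subset="snp_id").set_index("snp_id")
    e = eqtl.drop_duplicates(subset="snp_id").set_index("snp_id")
    shared = g.index.intersection(e.index)
    rows = []
    lo, hi = drop_palindromic_band
    for sid in shared:
        gr, er = g.loc[sid], e.loc[sid]
        ga, go = gr["effect_allele"], gr["other_allele"]
        ea, eo = er["effect_allele"], er["other_allele"]
        if (ga, go) in _PALINDROMES and lo <= float(gr["eaf"]) <= hi:
            continue
        if (ea, eo) == (ga, go):
            flip = 1.0
        elif (ea, eo) == (go, ga):
            flip = -1.0
        else:
            continue
        rows.append(
            {
                "snp_id": sid,
                "beta_gwas": float(gr["beta"]),
                "se_gwas": float(gr["se"]),
                "beta_eqtl": flip * float(er["beta"]),
                "se_eqtl": float(er["se"]),
                "eqtl_p": float(er["pvalue"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ColocResult:
    """Posterior over colocalization hypotheses for one gene region."""

    gene_id: str
    region: tuple[str, int, int]
    n_snps: int
    pp: dict[str, float]
    top_snp: str
    top_snp_posterior: float
    priors: tuple[float, float, float]
    w_gwas: float
    w_eqtl: float

    @property
    def pp_shared(self) -> float:
        return self.pp["H4"]

    @property
    def colocalized(self) -> bool:
        return self.pp_shared > 0.8


def coloc_region(
    gwas_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    gene_id: str = "",
    region: tuple[str, int, int] | None = None,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w_gwas: float = 0.2,
    w_eqtl: float = 0.15,
    min_snps: int = 10,
) -> ColocResult | None:
    """Five-hypothesis colocalization for one region; None when skipped.

    Regions with fewer than ``min_snps`` shared SNPs after harmonization
    are skipped with a logged reason.
    """
    merged = harmonize(gwas_stats, eqtl_stats)
    if len(merged) < min_snps:
        logger.info(
            "coloc %s skipped: %d shared SNPs after harmonization (< %d)",
            gene_id or "<region>", len(merged), min_snps,
        )
        return None
    merged = merged.drop_duplicates(subset="snp_id")
    l1 = np.array(
        [wakefield_abf(b, s, w_gwas) for b, s in zip(merged["beta_gwas"], merged["se_gwas"])]
    )
    l2 = np.array(
        [wakefield_abf(b, s, w_eqtl) for b, s in zip(merged["beta_eqtl"], merged["se_eqtl"])]
    )
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # log sum over ordered distinct pairs: sum_i sum_{j != i} e^{l1_i + l2_j},
    # computed as log(e^{s1+s2} - e^{s12}) with an explicit max shift; the
    # difference underflows to zero when one SNP dominates both traits
    shift = max(s1 + s2, s12)
    diff = np.exp(s1 + s2 - shift) - np.exp(s12 - shift)
    lh3_sum = shift + np.log(diff) if diff > 0 else -np.inf
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + lh3_sum,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    snp_post = np.exp(l1 + l2 - s12)
    top = int(np.argmax(snp_post))
    if region is None:
        region = ("", 0, 0)
    return ColocResult(
        gene_id=gene_id,
        region=region,
        n_snps=len(merged),
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        top_snp=str(merged["snp_id"].iloc[top]),
        top_snp_posterior=float(snp_post[top]),
        priors=(p1, p2, p12),
        w_gwas=w_gwas,
        w_eqtl=w_eqtl,
    )


def coloc_screen(
    gwas_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 500_000,
    **kwargs,
) -> list[ColocResult]:
    """Run coloc_region for every gene over TSS +/- window."""
    results = []
    for rec in genes.itertuples(index=False):
        lo, hi = rec.tss - window, rec.tss + window
        gsub = gwas_stats[
            (gwas_stats["chrom"] == rec.chrom)
            & gwas_stats["pos"].between(lo, hi)
        ]
        esub = eqtl_stats[
            (eqtl_stats["gene_id"] == rec.gene_id)
            & eqtl_stats["pos"].between(lo, hi)
        ]
        res = coloc_region(
            gsub, esub, gene_id=rec.gene_id, region=(rec.chrom, lo, hi), **kwargs
        )
        if res is not None:
            results.append(res)
    return results
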