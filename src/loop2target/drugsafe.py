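"""Directional druggability classification and PheWAS safety flagging.

A candidate causal gene whose higher expression raises disease risk
(MR beta > 0, or a colocalized variant where the expression-raising
allele also raises risk) needs an expression-lowering drug - an
antagonist/inhibitor; the opposite direction needs an agonist.  The
gene's strongest instrument (lowest eQTL p), or the coloc-prioritized
variant, is then screened phenome-wide: traits passing per-SNP
Benjamini-Hochberg FDR 5% become safety flags, each annotated with
whether the allele mimicking the therapy (moving expression in the
therapeutic direction) increases that trait's risk (adverse) or lowers
it (beneficial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .colocal import ColocResult
from .mrcausal import MRResult
from .util import bh_adjust

logger = logging.getLogger("loop2target.drugsafe")

_INHIBIT_TYPES = {"inhibitor", "antagonist"}
_ACTIVATE_TYPES = {"agonist"}


@dataclass
class SafetyFlag:
    trait: str
    p: float
    bh_fdr: float
    harm_direction: str  # "adverse" | "beneficial"


@dataclass
class TargetVerdict:
    """Directional druggability and safety verdict for one gene."""

    gene_id: str
    direction_source: str  # "MR" | "coloc"
    risk_direction: int  # +1: higher expression -> higher risk
    needed_modality: str  # "inhibit" | "activate"
    instrument_snp: str = ""
    instrument_eqtl_beta: float = float("nan")
    drugs: list[tuple[str, str]] = field(default_factory=list)  # (drug, type)
    unknown_drugs: list[str] = field(default_factory=list)
    modality_available: bool = False
    safety_flags: list[SafetyFlag] = field(default_factory=list)


def _modality(risk_direction: int) -> str:
    return "inhibit" if risk_direction > 0 else "activate"


def classify_modality(
    mr_results: list[MRResult],
    coloc_results: list[ColocResult],
    eqtl_direction: dict[tuple[str, str], float] | None = None,
    gwas_direction: dict[str, float] | None = None,
) -> list[TargetVerdict]:
    """Determine risk direction and needed drug modality per candidate gene.

    MR genes use sign(beta_ivw).  Coloc-only genes use
    sign(eqtl_beta * gwas_beta) at the prioritized SNP, looked up from
    ``eqtl_direction`` ((gene, snp) -> eqtl beta) and ``gwas_direction``
    (snp -> gwas beta) on the harmonized effect allele; genes with
    neither line of evidence are excluded with a log line.
    """
    eqtl_direction = eqtl_direction or {}
    gwas_direction = gwas_direction or {}
    verdicts: dict[str, TargetVerdict] = {}
    for r in mr_results:
        if r.beta_ivw == 0:
            logger.info("gene %s has MR beta exactly 0; excluded", r.gene_id)
            continue
        direction = 1 if r.beta_ivw > 0 else -1
        best = min(r.instruments, key=lambda iv: iv.eqtl_p)
        verdicts[r.gene_id] = TargetVerdict(
            gene_id=r.gene_id,
            direction_source="MR",
            risk_direction=direction,
            needed_modality=_modality(direction),
            instrument_snp=best.snp_id,
            instrument_eqtl_beta=best.beta_x,
        )
    for c in coloc_results:
        if c.gene_id in verdicts:
            continue
        eb = eqtl_direction.get((c.gene_id, c.top_snp))
        gb = gwas_direction.get(c.top_snp)
        if eb is None or gb is None or eb == 0 or gb == 0:
            logger.info(
                "gene %s (coloc) lacks directional evidence at %s; excluded",
                c.gene_id, c.top_snp,
            )
            continue
        direction = 1 if eb * gb > 0 else -1
        verdicts[c.gene_id] = TargetVerdict(
            gene_id=c.gene_id,
            direction_source="coloc",
            risk_direction=direction,
            needed_modality=_modality(direction),
            instrument_snp=c.top_snp,
            instrument_eqtl_beta=float(eb),
        )
    return list(verdicts.values())


def match_drugs(
    verdicts: list[TargetVerdict], drug_table: pd.DataFrame
) -> list[TargetVerdict]:
    """Join drug-gene interactions and assess modality compatibility.

    antagonist/inhibitor interactions satisfy an "inhibit" need; agonist
    satisfies "activate"; interactions of unknown type never satisfy the
    modality and are listed separately.
    """
    by_gene = dict(tuple(drug_table.groupby("gene"))) if len(drug_table) else {}
    for v in verdicts:
        v.drugs = []
        v.unknown_drugs = []
        v.modality_available = False
        sub = by_gene.get(v.gene_id)
        if sub is None:
            continue
        compatible = _INHIBIT_TYPES if v.needed_modality == "inhibit" else _ACTIVATE_TYPES
        for rec in sub.itertuples(index=False):
            itype = str(rec.interaction_type).lower()
            if itype == "unknown":
                v.unknown_drugs.append(rec.drug)
                continue
            v.drugs.append((rec.drug, itype))
            if itype in compatible:
                v.modality_available = True
    return verdicts


def phewas_flags(
    verdicts: list[TargetVerdict],
    phewas_table: pd.DataFrame,
    fdr: float = 0.05,
) -> list[TargetVerdict]:
    """Per-SNP phenome-wide safety screen at BH FDR < ``fdr``.

    BH correction is applied within each SNP across all its traits.  The
    harm direction compares the PheWAS effect of the therapy-mimicking
    allele: for an "inhibit" gene the therapy mimics the
    expression-lowering allele, so a trait whose risk rises when
    expression falls (sign(phewas_beta) opposite to sign(eqtl_beta)) is
    adverse; symmetric for "activate".
    """
    by_snp = dict(tuple(phewas_table.groupby("snp"))) if len(phewas_table) else {}
    for v in verdicts:
        v.safety_flags = []
        sub = by_snp.get(v.instrument_snp)
        if sub is None:
            logger.info(
                "instrument %s of %s absent from PheWAS table", v.instrument_snp, v.gene_id
            )
            continue
        adj = bh_adjust(sub["p"].to_numpy())
        # therapeutic direction of expression: -risk_direction; the allele
        # moving expression that way has eqtl sign -risk_direction relative
        # to the recorded effect allele
        for (rec, a) in zip(sub.itertuples(index=False), adj):
            if a >= fdr:
                continue
            mimic_sign = -v.risk_direction * (1 if v.instrument_eqtl_beta > 0 else -1)
            trait_effect_of_mimic = mimic_sign * (1 if rec.beta > 0 else -1)
            harm = "adverse" if trait_effect_of_mimic > 0 else "beneficial"
            v.safety_flags.append(
                SafetyFlag(trait=rec.trait, p=float(rec.p), bh_fdr=float(a), harm_direction=harm)
            )
    return verdicts


def verdict_table(verdicts: list[TargetVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "gene_id": v.gene_id,
                "direction_source": v.direction_source,
                "risk_direction": v.risk_direction,
                "needed_modality": v.needed_modality,
                "instrument_snp": v.instrument_snp,
                "n_drugs": len(v.drugs),
                "modality_available": v.modality_available,
                "n_safety_flags": len(v.safety_flags),
                "adverse_flags": ";".join(
                    f.trait for f in v.safety_flags if f.harm_direction == "adverse"
                ),
            }
        )
    return pd.DataFrame(rows)
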