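# loop2target

From GWAS loci to druggable genes: an integrative pipeline that chains
genome-wide association signals, enhancer–promoter chromatin loops,
cis-eQTLs, Bayesian colocalization, and two-sample Mendelian
randomization into a ranked, safety-screened list of candidate drug
targets for vascular disease.

The package is aimed at statistical geneticists and computational
biologists who want a desk-scale, fully testable implementation of this
kind of target-prioritization workflow: every stage runs on synthetic
data with known ground truth, so each estimator can be validated by
parameter recovery rather than by eyeballing.

## The pipeline

1. **Clumping** (`ldtools`) — greedy FUMA/PLINK-style definition of
   independent significant SNPs (P < 5×10⁻⁸, pairwise r² < 0.6,
   MAF ≥ 0.01), lead SNPs (r² < 0.1), and merged genomic risk loci
   (boundary gap < 250 kb), with LD computed from a genotype reference
   panel.
2. **3D SNP-to-gene mapping** (`chrom3d`) — FitHiChIP-style loops
   (5-kb anchor bins, FDR < 10⁻⁶) connect trait SNPs in one anchor to
   gene promoters (TSS ± 2 kb) overlapping the other anchor; hub
   enhancers are anchors at or above the 90th-percentile degree;
   projection (binomial) and hub-enrichment tests quantify overlap with
   open chromatin and association signal.
3. **Partitioned heritability** (`heritability`) — a compact stratified
   LD-score regression: GWAS χ² regressed on annotation-stratified LD
   scores, with a delete-one-block jackknife for the enrichment CI.
4. **cis-eQTL mapping** (`eqtlmap`) — independent significant SNPs
   joined to genes within ±500 kb of the TSS at joint BH FDR 5%, plus a
   binomial enrichment of the 3D and eQTL gene sets.
5. **Colocalization** (`colocal`) — per-gene five-hypothesis Bayesian
   colocalization from Wakefield approximate Bayes factors over
   TSS ± 500 kb; a region is colocalized when PP(H4) > 0.8.
6. **Mendelian randomization** (`mrcausal`) — instruments are cis-eQTLs
   with p < 0.001, pruned at r² < 0.1, minimum three per gene; the
   inverse-variance-weighted estimate

   β̂_IVW = Σ θ̂ⱼ σⱼ⁻² / Σ σⱼ⁻²,  θ̂ⱼ = β̂_yⱼ / β̂_xⱼ,  σⱼ = se(β̂_yⱼ)/|β̂_xⱼ|

   is screened at BH FDR 5%, filtered on Cochran's Q heterogeneity
   (p > 0.05), and checked against the weighted-median estimator, which
   stays consistent with up to half the instrument weight invalid.
7. **Network prioritization** (`netprior`) — candidate causal genes seed
   a first-order PPI subnetwork; hub genes (≥ 90th-percentile degree),
   hypergeometric seed–hub enrichment, and Walktrap communities with
   per-community seed enrichment.
8. **Druggability and safety** (`drugsafe`) — the sign of the causal
   effect dictates the therapeutic modality (higher expression → higher
   risk ⇒ inhibit; the opposite ⇒ activate), matched against a drug–gene
   interaction table; each target's strongest instrument is screened
   phenome-wide, flagging traits at per-SNP BH FDR 5% and annotating
   whether the therapy-mimicking allele raises their risk.

`simulate` generates every input with known ground truth — a block-LD
genotype panel, per-gene cis-eQTL architectures, a liability-threshold
case/control GWAS whose per-gene causal effect is exactly the planted
log-odds per SD of expression, loop networks with designated hubs, a
scale-free PPI, and drug/PheWAS lookup tables.

## Worked example

The default configuration simulates a 12-Mb genome (1,200 markers in
50-kb LD blocks), 60 genes, a 2,000-sample eQTL study and a
20,000-sample case/control GWAS, with three planted causal genes —
GENE0010 (η = +0.5), GENE0030 (+0.5, carrying a planted adverse PheWAS
trait), GENE0050 (−0.5) — and runs end to end in well under a minute:

```bash
loop2target run --seed 1 --outdir demo
# run complete: 3 candidate causal genes -> demo/report.json
```

The MR screen (`demo/mr.tsv`) reports, for the causal set:

```
 gene_id  k  or_ivw  or_lo95  or_hi95  p_het  causal
GENE0010  3   1.635    1.503    1.778  0.349    True
GENE0030  4   1.548    1.425    1.682  0.736    True
GENE0050  3   0.602    0.550    0.660  0.615    True
```

i.e. odds ratios per SD of expression of 1.63, 1.55 and 0.60 — the
planted effects e^±0.5 ≈ 1.65 / 0.61 recovered within sampling error —
with no heterogeneity flag. All three genes also colocalize at
PP(H4) ≈ 1.0. The final target report (`demo/targets.tsv`) assigns
inhibition to the two risk-increasing genes and activation to the
protective one, finds a compatible compound for each, and attaches the
planted adverse flag (trait_007) to GENE0030's instrument — the
simulated analogue of a target whose inhibition would trade one disease
for another. Along the way the pipeline reports, for example, a
peak–anchor projection enrichment of 4.9-fold (p ≈ 10⁻¹¹⁷) and a
20-fold enrichment of eQTL genes among loop-mapped genes.

Each stage can also be run separately (`loop2target simulate`, `clump`,
`map3d`, `h2`, `eqtl`, `coloc`, `mr`, `network`, `drug`, `report`) from
the same `--config`/`--seed`/`--outdir`, reading only the files written
by earlier stages; `manifest.json` records parameters, input hashes,
output row counts and wall times per stage.

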