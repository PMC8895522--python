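# Methods

This note records the models, estimators, numerical choices and known
limitations behind `loop2target`, in the order the pipeline runs.

## Synthetic data model

**Genotype panel.** Haplotypes are latent Gaussian AR(ρ_b) processes per
LD block, thresholded at the allele-frequency quantile (so the alternate
allele has probability equal to the variant's EAF) and summed into
dosages in {0,1,2}. Cross-block LD is zero in expectation; ρ can be a
single value or a (low, high) range from which per-block correlations
are drawn, emulating the LD heterogeneity of real genomes. Thresholding
a latent Gaussian attenuates the dosage-scale correlation below ρ: for
matched common alleles the phi coefficient is ≈ (2/π)·arcsin(ρ), so at
ρ = 0.9 the adjacent dosage r² concentrates near 0.5 rather than 0.81,
and lower for rare alleles. This attenuation is intrinsic to the
construction and is why the default pipeline treats ρ ranges of roughly
0.2–0.7 as "realistic LD". The default pipeline genome has 1,200 markers
10 kb apart in 5-variant (50-kb) blocks over 12 Mb; validation
simulations use up to 20,000 markers.

**cis-eQTL architecture.** Each gene receives `k_causal` cis causal
variants (±500 kb of the TSS) with raw per-allele effects
N(0, β_sd²); expression is y = Xβ + ε, standardized before the marginal
scan, so reported effects and the stored ground truth are per allele on
the SD-of-expression scale. Planted (intentionally causal) genes instead
get fixed effects with a dominant primary variant (1.25× / 0.75× of the
configured mean effect), one variant per LD block, restricted to common
variants (EAF ≥ 0.2), and their blocks are withheld from other genes'
causal sampling. Those four choices are deliberate scenario design: the
primary-plus-secondary structure is the common real cis architecture and
keeps regions compatible with single-causal-variant colocalization;
one-variant-per-block guarantees the gene survives LD pruning with ≥ 3
instruments; common variants keep instrument strength stable in finite
samples; and block exclusivity preserves the exclusion restriction of
the planted instruments (otherwise a neighbouring gene's random eQTL in
the same block inherits genuine outcome signal and becomes a systematic
false positive rather than a calibrated one).

**Disease GWAS.** Liability is Σ_g η_g · (genetically predicted
standardized expression) + Σ pleiotropic variant effects + ε with ε
standard logistic; cases are individuals above the (1 − prevalence)
liability quantile (default prevalence 0.22). With logistic noise the
conditional log-odds per SD of expression equals η_g exactly, so the MR
estimand is the planted η_g up to the mild noncollapsibility of marginal
logistic effects — absorbed by the 3-SE recovery tolerance used in the
tests. Marginal per-variant logistic regressions are fitted by a
vectorized Newton–Raphson scan (verified against statsmodels to ~1e-6).
A separate generator (`simulate_chi2_sumstats`) draws quantitative-trait
z-scores directly from the LD-score model z = √N·R·b + e for the
heritability-partition validations.

**Loops, peaks, networks, lookup tables.** Promoter bins are looped to
nearby enhancer bins on a 5-kb grid, with a configurable fraction of
enhancer–enhancer loops; designated hubs receive extra partners by
preferential attachment; q-values are drawn log-uniformly on either side
of the 10⁻⁶ cut. The causal eQTLs of every gene are wired into
promoter loops, realizing the enhancer-variant → loop → promoter
mechanism the 3D mapping stage is meant to detect. ATAC-like peaks
overlap anchors at a configurable rate over background. The PPI uses a
configuration model on a truncated power-law degree sequence (exponent
γ), which preserves the sampled tail; the PheWAS table is per-(SNP,
trait) with uniform null p-values and optionally planted associations.
All generators are bit-reproducible; every stream is derived from one
master seed by a CRC32-named child-seed scheme so each generator can be
re-run in isolation.

## Estimators and tests

**Clumping** is the greedy accept-if-independent scan in ascending-p
order, with ties broken by (chrom, pos, snp_id) for platform-stable
output. MAF is taken from the panel, not the summary statistics,
mirroring the use of an external LD reference. All thresholds are strict
(<) except MAF (≥).

**3D mapping** uses 0-based half-open intervals throughout (1-based
positions converted on input); touching intervals do not overlap. A
(snp, gene) pair is emitted once per loop in which the SNP lies in one
anchor and the promoter intersects the other; enhancer–promoter distance
is between anchor midpoints (a symmetric choice; the measure is not
standardized in the field). Hub calling takes the nearest-rank
percentile over the full distinct-partner degree census with ties
included; on degenerate censuses (most nodes sharing the minimum degree)
the 90th-percentile threshold can equal that minimum and every node
qualifies — the definition is aimed at heavy-tailed censuses, where it
returns the top decile. The projection test reduces queries to midpoints
and uses a two-sided exact binomial against the merged reference
coverage; the SNP–hub and 3D/eQTL overlap enrichments use upper-tail
exact binomials, and seed–hub enrichment the upper-tail hypergeometric.

**S-LDSC-lite** regresses χ² = (β/se)² on {N·ℓ(j,c)} with an intercept,
weights 1/max(1, ℓ_base)², and the finite-sample-unbiased
r²_adj = r² − (1 − r²)/(n − 2) summed within a 1-Mb window (sums
truncated below at the self term). Differences from the reference
implementation, chosen for a compact synthetic genome: two annotations
by default instead of the 53-annotation baseline (extra columns are
accepted); simple inverse-ℓ² weights instead of iterated
heteroskedasticity weights (efficiency, not consistency); 20 contiguous
jackknife blocks instead of 200. Enrichment is (share of h²)/(share of
SNPs) with a jackknife SE and a t-test against 1; both the point
estimate and the CI are reported. The intercept and the base coefficient
are separable only when ℓ_base varies across variants — on a genome with
homogeneous blocks they are nearly collinear and the enrichment ratio is
unstable, which is why the validation genome draws per-block ρ from
(0.1, 0.8).

**Colocalization** is the classical two-trait single-causal-variant
five-hypothesis enumeration with Wakefield log-ABFs
(½[log(1−r) + z²r], r = W²/(W²+se²)), log-sum-exp accumulation, priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, and prior effect SDs W = 0.2 (case/control)
and 0.15 (eQTL). The H3 term log(e^{s1+s2} − e^{s12}) is computed with
an explicit max shift and clamped to −∞ when the difference underflows
(one SNP dominating both traits). Alleles are harmonized before
intersection: effects sign-flipped on swapped alleles, strand-ambiguous
A/T–C/G SNPs dropped when EAF ∈ [0.4, 0.6]. Regions with fewer than 10
shared SNPs are skipped with a logged reason. With multiple shared
causal variants of similar strength the single-variant model can prefer
H3; a dominant shared variant restores H4 — a known limitation inherited
from the model class.

**Mendelian randomization.** Fixed-effect (first-order-weight) IVW on
Wald ratios; equivalent to weighted zero-intercept regression (tested to
1e-10). Instruments are ordered by exposure p for the greedy LD prune,
instruments with β_x = 0 are dropped with a warning, and genes with
fewer than three instruments are skipped and excluded from the BH
denominator. Cochran's Q uses the χ²_{k−1} upper tail. The weighted
median interpolates the ordered ratios at cumulative midpoint weight
0.5; its SE is a parametric bootstrap (θ_j ~ N(θ̂_j, σ_j²), 1,000 draws,
fixed seed), vectorized but numerically identical to per-draw
interpolation. Its robustness guarantee is asymptotic in the number of
instruments: with a finite panel and 40% invalid weight the estimate
sits at the ≈ (0.5/0.6) quantile of the valid cluster, so its residual
bias scales with the ratio SE — the validation uses precise outcome
estimates, the regime the estimator is designed for. The causal set
requires BH FDR < 5% and Q p > 0.05.

**Communities** come from igraph's Walktrap (4-step walks, dendrogram
cut at maximal modularity) on the networkx graph, with per-community
upper-tail hypergeometric seed enrichment; the module p-value definition
is our interpretation, as the upstream tool does not document one.

**Druggability and safety.** Risk direction is sign(β_IVW) for MR genes
and sign(β_eQTL·β_GWAS) at the coloc-prioritized SNP for coloc-only
genes (MR takes precedence when both exist); inhibit ⟺ positive risk
direction. Antagonist/inhibitor interactions satisfy an inhibit need,
agonists an activate need, unknown types never (listed separately).
PheWAS BH correction is per SNP across traits; the harm direction asks
whether the allele moving expression in the therapeutic direction
raises the flagged trait's risk, and is invariant to allele recoding.

## Pipeline and defaults

Stages exchange files only (TSV with header and '.' for missing; BED and
BEDPE 0-based half-open and headerless, as those formats require); the
run manifest records parameters, input hashes, output row counts and
wall times. The candidate causal set is the union of colocalized genes
(PP(H4) > 0.8) and MR-causal genes (FDR < 5%, Q p > 0.05). Colocalization
and MR are screened over all annotated genes, with the 3D and eQTL maps
reported alongside as regulatory evidence, so discovery power does not
hinge on genome-wide-significant clump membership at desk scale.

Default scenario (chosen once as the package's study conditions): 500
reference individuals, 60 genes, n_eqtl = 2,000, n_gwas = 20,000 at
prevalence 0.22, three planted genes at η = ±0.5 with mean planted eQTL
effect 0.4, enhancer density 0.12, hub fraction 0.05, 778 PheWAS traits,
PPI exponent 2.5. The planted-scenario probabilities are not exactly 1:
a null gene can pass BH behind three strong true positives with
probability on the order of q·k_true, and the three planted genes carry
the usual 5% per-gene chance of a spurious Q rejection (with coloc as
the rescue route). Validation problem sizes (200-gene MR screens at
n_gwas = 20,000; 20,000-variant heritability genome; 200 coloc regions;
2,000 Q replicates) were chosen to keep the full suite comfortably
within a desktop run while leaving Monte-Carlo margins well away from
the asserted bounds.

## What passing tests do and do not show

The generators emulate the statistical structure of the real inputs —
block LD, per-gene cis architectures, gene-mediated case/control
effects, heavy-tailed anchor degree, scale-free PPI — but not their
biology: no real coordinates, no population structure or relatedness,
no covariates in the GWAS (the emulated study adjusted for age, sex and
principal components), no read-level noise, no allele-frequency
spectrum matching, and trans effects, multi-causal coloc regions and
correlated pleiotropy appear only where a test plants them. Passing
therefore demonstrates that the estimators are implemented correctly
and calibrated under their stated assumptions, not that those
assumptions hold in any particular real dataset.
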