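# Methods

## Model and procedure

`pathgwas` implements the modified gene-set enrichment approach to
pathway-based GWAS. The observable is a genome-wide gene ranking built
from single-marker association statistics; the inferential question is
whether a pre-defined gene set is concentrated at the top of that ranking
more than phenotype-label permutation would produce.

**Single-marker layer.** For a dichotomous phenotype the test is the
1-df allelic chi-square on the 2×2 allele-count table (each sample
contributes two alleles). For a quantitative phenotype it is the F
statistic (1, n−2 df) of ordinary least squares of the prepared trait on
additive dosage; by the t² identity this ranks SNPs identically to the
regression t/Wald test. Missing genotypes are dropped pairwise.
Monomorphic SNPs have no defined statistic: they are flagged, reported
with statistic 0 and P 1, and never allowed to represent a gene.

**Hardy–Weinberg QC.** The HWE filter uses the exact conditional test:
all heterozygote counts compatible with the observed allele counts are
enumerated, and the P value is the total probability of tables no more
probable than the observed one. Computation is in log-space with a
gammaln-based expression of the table probability, so counts in the
thousands are exact to floating precision. SNPs with MAF < 0.01 or HWE
P < 0.001 are removed before anything downstream.

**Phenotype preparation.** Outlier removal is a single pass on the raw
trait (|t − mean| > 3 SD excluded; no iterative re-estimation). The
covariate-adjusted mode regresses trait on covariate once and
standardizes the residuals (sample SD, ddof = 1) to mean 0 / SD 1; this
transform is fixed before inference, and permutations shuffle the
*prepared* values — the covariate fit is not repeated per permutation.
Dichotomization uses strict inequalities on both thresholds, so boundary
values fall into the gray zone and are excluded; defaults (10.4 / 7.4)
follow the plasma-adiponectin case/control convention.

**Gene scores and ranking.** A SNP maps to a gene when it lies on the
same chromosome within the gene span extended by 20 kb on each side,
with both extended boundaries inclusive (a closed-interval reading of
"the flank is part of the gene"; the literature does not fix the boundary
convention, so this is a documented choice, not a claim). A SNP may map
to several genes. Each gene's representative statistic is the maximum
over its mapped, non-flagged SNPs; genes are ranked descending with ties
broken by ascending gene id — enrichment depends on rank order, so the
tie-break must be deterministic.

**Enrichment score.** For set S with N_H of the N ranked genes, the
running sum adds |r(j)|^p / N_R at member ranks (N_R = Σ_S |r|^p,
default p = 1) and subtracts 1/(N − N_H) elsewhere; ES is the maximum
over the walk (one-sided: enrichment at the top of the list, not
depletion). At p = 0 this reduces to the classical unweighted KS running
statistic. ES = 1 exactly when all members precede all non-members.

**Permutation null and significance.** K phenotype-label permutations
(default 1000) rerun the SNP statistics, gene maxima, ranking and ES.
Genotypes, the QC mask, the SNP→gene index and the gene universe do not
depend on the phenotype, so they are computed once; each permutation is a
matrix of shuffled phenotype columns scored with a handful of matrix
products. Per set, NES = (ES − mean_k ES_k)/SD_k ES_k (population SD,
ddof = 0, making per-set permutation NES exactly mean 0 / SD 1);
empirical P uses the add-one estimator (1 + #{ES_k ≥ ES_obs})/(K + 1),
rendered `<1/K` when no permutation reaches the observed score. The FDR
at NES* is the pooled-null exceedance fraction divided by the observed
exceedance fraction, clipped to [0, 1] and made monotone non-increasing
in NES* by a running minimum (the raw ratio can invert locally); the
FWER is the fraction of permutations whose maximum NES across sets
reaches NES*. Sets whose permutation ES has zero SD have undefined NES
and are excluded from pooling. Gene sets are restricted to members
present in the ranked universe, with effective sizes bounded to
[10, 200] by default (configurable).

**Replication from summary statistics.** When only per-SNP P values are
available, each gene scores −log10 of its k-th smallest P (k = 2 by
default, the convention of the summary-statistic pathway tools this mode
mirrors, damping single-SNP artifacts; genes with fewer than k SNPs fall
back to their largest available order statistic). Each set is tested
with z = (mean member score − mean universe score)/(universe SD/√m) and
a one-sided upper-tail normal P, then BH-corrected. The null mean/SD come
from the empirical gene-score universe rather than SNP-level resampling —
the simple Z form; its normal approximation leans on m ≥ 10 and is the
reason set-size bounds apply here too.

## Randomness and reproducibility

One master seed spawns an independent child stream per permutation
(`SeedSequence.spawn`), so raising K extends the null without altering
earlier permutations, and the whole pipeline is bit-reproducible for a
fixed configuration. Reports carry the configuration digest and seed in
their `#` header and are byte-identical across reruns.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes:
biallelic SNPs in HWE with MAF ~ Uniform(0.05, 0.5) and no LD
(independent sites), genes tiled without overlap along a chromosome
(50 kb gaps keep ±20 kb windows disjoint) with SNPs placed inside spans
plus extras in flanks and deep-intergenic space to exercise the window
logic, pathways of 10–20 genes drawn from a 200-gene pool, and a trait
y = Σ β(g − 2f) + γc + ε with one causal SNP per causal gene, a standard
normal covariate and Gaussian noise. The default study condition —
500 samples, 2000 SNPs, 200 genes, 50 pathways, β = 0.5 and noise SD 1
in the causal scenario — is large enough for the permutation machinery to
be exercised honestly yet runs in seconds per cohort on one core.

Because sites are independent and the max-SNP rule uses one SNP per
gene, the brute-force oracles in the tests are exact; passing them says
the formulas are implemented correctly. It does **not** certify behavior
on real data with LD blocks (where neighboring genes share signal and
gene windows capture correlated SNPs), population structure, relatedness
or imputation uncertainty — all deliberately outside the generator.

## Numerical choices

- Association P values are floored at 1e-300; perfect regression fits
  clip the residual sum of squares at a relative 1e-14 so the F statistic
  stays finite.
- The HWE exact P includes ties with a 1e-12 relative slack so
  equally-probable tables are always counted.
- The quantitative statistics are computed from sufficient sums with the
  missingness mask folded into the matrix products, so the permutation
  matrix path and the single-column path are the same arithmetic.
- PED input codes dosage against the minor allele; at an exact frequency
  tie the lexicographically larger allele counts as minor.
- BED annotation is 0-based half-open on disk and converted to 1-based
  inclusive at the reader.

## Limitations

- Single-covariate adjustment only; no multi-covariate or mixed models.
- The binary test is the allelic chi-square (no trend/genotypic
  alternatives), and enrichment is one-sided.
- The summary-statistic Z test is an approximation whose calibration on
  real data depends on gene-score dependence induced by LD and shared
  SNPs; the package reports it as the replication-mode convention, not as
  an exact test.
- Reported empirical P values cannot go below 1/(K+1); findings at that
  floor are resolution-limited, not "zero".
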