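# Methods

This note documents the statistical procedures implemented in `pathmeld`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical decisions a maintainer would want
written down.

## Genotype QC and annotation

Dosages are minor-allele counts in {0, 1, 2} with −1 as the missing code;
the minor allele is determined from the full sample, with ties at
MAF = 0.5 broken to `allele2` for determinism. QC removes SNPs with call
rate < 0.90, MAF < 0.01, or Hardy–Weinberg exact p < 10⁻⁴ computed in
controls only. The HWE test enumerates every heterozygote count compatible
with the observed allele totals in log space and sums conditional
probabilities no larger than the observed table's (with a 1 + 10⁻¹²
relative tolerance on the equality comparison to absorb rounding).
Coordinates are 1-based, closed intervals; gene windows (default ±20 kb)
are boundary-inclusive and strand-ignorant, and a SNP inside several
overlapping gene windows is assigned to all of them — pathway SNP sets
deduplicate, so a SNP contributes once per pathway.

## Single-SNP association and interactions

The Cochran–Armitage trend statistic with additive scores (0, 1, 2) is
computed in the score-test form χ² = U²/V (the exact form used by R's
`prop.trend.test`, against which it is frozen in the tests). Missing
genotypes drop out per SNP; monomorphic SNPs get χ² = 0, p = 1, and never
qualify as set contributors. Genomic control divides all chi-squares by
λ = median(χ²)/0.4549 only when λ > 1.

MDR labels each multilocus genotype cell high-risk when its training
case:control ratio reaches the overall training ratio; empty cells are
low-risk (the conservative convention). Models are scored by testing
balanced accuracy — robust to case/control imbalance — over stratified,
seeded cross-validation folds; per-fold winners are chosen by training
balanced accuracy, and the reported consistency is the number of folds the
best-by-mean-test-accuracy model won. The permutation p re-runs the whole
search on permuted phenotypes.

## Pathway-level GWAS statistics

All permutation p-values use the (1 + b)/(1 + n) estimator, so no test can
report p = 0 and the test remains valid at any permutation count. Within a
run, one shared stream of permuted phenotype labelings serves every set,
which makes p-values comparable between sets and keeps the cost at one
vectorized trend-test pass per permutation (genotype column totals do not
depend on the labels, so each permutation needs only three matrix
products).

*Set-based test.* Members are LD-pruned greedily in ascending-p order
(keep a SNP iff its dosage r² with every kept SNP is below the threshold,
default 0.5); up to N SNPs with p ≤ 0.05 are selected by ascending p and
their mean χ² is the statistic, with selection redone inside every
permutation. N = 5 for gene-level runs and N = 20 for pathway-level runs.
Sets with no qualifying SNP score 0 and report p = 1 — under the null this
leaves a small conservative atom at p = 1, which shrinks as sets grow.

*Max-SNP enrichment.* Gene statistic = max member-SNP χ²; genes are ranked
(ties broken by symbol) and each pathway scored by the weighted KS
enrichment score (weight 1). A set covering every ranked gene is
uninformative and scores 0. The empirical p is one-sided against the
pathway's own phenotype-permutation ES distribution.

*Interval enrichment.* LD clumping processes index SNPs (p ≤ 0.01) in
ascending-p order; each absorbs unassigned same-chromosome SNPs with
p ≤ 0.05 and r² ≥ 0.5, so intervals are SNP-disjoint by construction. The
statistic per pathway counts intervals overlapping ≥ 1 member gene
(windowed). Null intervals are windows of consecutive SNPs relocated
uniformly over the SNP map, matched to the original on SNP count (±20%),
overlapping-gene count (exact), and SNP density per kb (±50%); when no
placement qualifies the tolerances are relaxed stepwise (gene-count match
dropped first, then both tolerances doubled, at most four rounds, each
logged) and as a last resort the interval is frozen in place. An
`exhaustive` mode enumerates all placement combinations for small genomes
and is checked against independent enumeration in the tests.

*Pre-ranked GSEA.* Gene-level empirical p-values are scored as
log₀.₀₅ p = ln p / ln 0.05 (1 at p = 0.05, 0 at p = 1); genes with p = 1
are removed before ranking. The engine walks the ranked list with hit
increments |score|ʷ (normalized over hits) and miss decrements
1/(n − n_hits); ES is the signed extremum of the running sum, with
magnitude ties resolved to the positive extremum. The null permutes gene
identities (equivalently, random same-size subsets), vectorized over
permutations by evaluating the running sum only at hit positions. The
nominal p is one-sided over same-sign null ES values — this keeps nominal
p uniform for random sets, which the calibration tests assert — NES
divides ES by the mean |null ES| of the same sign, and the FDR q is the
GSEA-style ratio of pooled-null to observed tail fractions clipped to
[0, 1]; a BH-adjusted q over nominal p's is emitted alongside. Default
weight 1.

## Monte-Carlo combination of correlated p-values

Pathways are ranked ascending by p within each method (average ranks on
ties, treating methods equally). The null simulates matrices of uniforms
with the methods' empirical Pearson correlation *A*: independent uniforms
are mapped to normal scores, mixed by the upper-triangular Cholesky factor
*L* (A = LᵀL), and mapped back through the normal CDF. Multiplying
uniforms directly by L would destroy marginal uniformity; the
normal-score (Gaussian copula) route preserves both marginals and, up to
the usual copula shrink, the target Pearson correlation — this is the
single largest interpretive decision in the package and is asserted
numerically in the tests. Each simulated matrix is ranked within columns
and averaged per row; all n_sim × n_pathways simulated average ranks pool
into one null, giving fine p resolution. Non-PSD sample correlation
matrices are repaired by eigenvalue clipping at 10⁻⁸; a single-method
matrix uses A = [[1]]. Methods that drop pathways have missing p-values
imputed as 1 before alignment (logged). Top pathways are the K = 20 best
combined p's among those < 0.05 (K shrinks with a warning if fewer
qualify).

Confounder diagnostics report Pearson correlations of combined p against
pathway size, and of per-gene SNP density (SNPs per kb of gene length)
against annotation degree and gene-level p, on original and log scales;
the bootstrap compares the top pathways' mean SNP density to draws of
equally many pathways resampled with replacement.

## Pathway deregulation scores

Counts are normalized by median-of-ratios size factors (the size factor of
a sample is the median over universally expressed genes of its count over
the gene's geometric mean) and log2(x + 1)-transformed. Per pathway, genes
present and variable (sd > 10⁻⁸ overall and among normals) are z-scored on
the normal samples' mean/sd; PCA keeps the smallest number of components
explaining 85% of variance (capped at 5); a principal curve is fitted
through all samples by the Hastie–Stuetzle iteration — PC1
initialization, alternating polyline projection and per-coordinate
smoothing against arc length until the mean squared projection distance
changes by less than 10⁻⁴ relative, at most 50 iterations. The local
smoother is a moving-window local *linear* fit over a 0.3 span: it exactly
reproduces linear data including at the boundaries (so scores on
perfectly collinear data equal the affinely rescaled PC1 coordinate to
machine precision, asserted at 10⁻⁶) and costs O(n) via cumulative sums —
a GCV-selected smoothing spline was measured to dominate the entire
pipeline's runtime for no accuracy gain on these data. The PDS of a
sample is its arc-length distance from the normal-median projection,
divided by total curve length, hence in [0, 1]; the absolute distance
makes the score orientation-free. Pathways with fewer than 3 usable genes
yield NaN rows. No additional standardization is applied to the PDS
matrix before testing.

The paired test uses the per-pathway paired t over (tumor − normal)
differences. The null reassigns each patient's (tumor, normal) PDS pairs
jointly to random pathways — the pairing never breaks — matching the
hypothesis that a pathway's PDS is exchangeable with other pathways'; the
alternative within-pair label flip is available behind `flip_pairs=True`.
Zero-variance differences give an undefined t and p = 1. BH q across
pathways.

## Survival

Patients strictly above the median PDS form the higher-risk group (ties
at the median go low). Kaplan–Meier estimation is delegated to lifelines;
the two-group weighted log-rank statistic is computed from hypergeometric
moments at each distinct event time with simultaneous tie handling, with
weight 1 (log-rank) or the number at risk (Gehan–Breslow–Wilcoxon, the
default reading of "Wilcoxon log-rank" and the default here). Degenerate
dichotomizations are flagged with p = 1. BH q pools all pathways analyzed
in the run.

## Cross-type consistency and stratification

Ranks within each data type come from whatever significance column that
data type provides (combined p for GWAS, nominal enrichment p for
mutation, empirical paired-test p for expression, log-rank p for
survival), with missing pathways imputed p = 1 before ranking. The null
resamples one rank per data type independently, deliberately destroying
cross-type dependence: the empirical p measures consistency against
independence. Enumeration mode reports the exact null probability (no MC
correction); sampling mode uses (1 + b)/(1 + n).

Pathway burden is the per-patient sum of minor-allele dosages over the
pathway's SNPs (missing dosages mean-imputed), z-scored per pathway, then
shifted by the global matrix minimum so the matrix is nonnegative — the
shift is global, not per row. NMF uses plain multiplicative updates on the
Frobenius objective (verified nonincreasing per iteration and equivalent
in reconstruction error to scikit-learn's MU solver), best of the random
restarts; the Frobenius objective was chosen over KL divergence because
the burden matrix is dense and roughly Gaussian after z-scoring, and a
side-by-side probe showed no labeling advantage for KL on these data.
Consensus clustering
runs 50 restarts per candidate rank by default (30 in the scaled-down
tests), assigns each patient to the argmax row of H per run, and picks the
rank maximizing the cophenetic correlation between 1 − consensus distances
and their average-linkage dendrogram (ties to the smaller rank); hard
labels cut that dendrogram. Subgroup tests default to Welch's t (subgroup
sizes are unequal in practice); the pooled-variance test is a flag away.

## Synthetic data

The generators are pure functions of (design, seed) and emit the exact
formats the readers consume. Defaults are desk-scale and are the study
conditions for all tests: 300 cases / 300 controls, 5,000 SNPs in LD
blocks of 10 (first-order allele copying with probability 0.8 — enough LD
to exercise pruning and clumping, not a human LD map), 500 genes tiled
along one chromosome, 40 contiguous-gene pathways, one planted pathway
(odds ratio 1.5 at 10 causal SNPs, Beta(0.1, 1) mutation p-values, 2-SD
expression shift along a fixed latent direction with per-patient severity
~ U(0.5, 1.5), hazard ∝ exp(1 × standardized severity)), 23 tumor/normal
pairs plus 100 unpaired tumors, and uniform censoring tuned by bisection
to a 40% rate. Phenotypes follow a logistic model and individuals are
drawn until the case/control quotas fill, emulating case/control
ascertainment.

What the generators do **not** emulate: realistic human LD structure and
allele-frequency spectra, population stratification, mutational
signatures, RNA-seq overdispersion beyond log-normal noise with library
size factors, or informative censoring. Passing tests therefore
demonstrate the statistical machinery — calibration under the null,
recovery of planted pathway-concentrated effects, determinism — not
performance on real cohort data.

## Problem sizes in the tests

The test suite scales simulations to desk size as the package's own
choice: permutation counts of 150–300 (the production default exposed in
`RunConfig` is 10,000-scale), 200 pathways or replicates for calibration
KS checks at α = 0.01, ten end-to-end replicates for planted-effect
recovery, and twenty replicates for stratification recovery. The
stratification recovery check at the planted 1.5-SD burden shift selects
the correct rank (2) and the correct driving pathways essentially always,
but the adjusted Rand index of the recovered labels plateaus near 0.5–0.65
— close to the ~0.7 ceiling that k-means with the true number of clusters
attains on identical draws, reflecting the overlap of the two planted
populations at that effect size rather than a defect of the consensus
procedure.

## Known limitations

Covariate adjustment (beyond genomic control), imputation, X-chromosome
handling, Cox regression, and model-based cross-omics integration are out
of scope. The GSEA engine implements gene-identity permutation only; the
interval-enrichment relocation null matches interval properties only
approximately, with logged tolerance relaxation; the principal-curve
fitting omits the published Pathifier refinements (spanning-tree
denoising, stability filtering over sample subsets), which matters little
for drift-along-a-direction deregulation but may for strongly nonlinear
real trajectories.
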