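# Methods

## The model

`evostrat` implements an *evolutionary stratified polygenic score* (ES-PGS)
analysis. A genome-wide polygenic score is the weighted allele count
`PGS_i = Σ_j g_ij β_j` over an approximately independent SNP set, where
`g_ij ∈ {0,1,2}` is the dosage of individual `i` at variant `j` and `β_j` the
GWAS effect weight aligned to the alt allele. The score is split into three
mutually exclusive partitions by genomic location:

* **annotation** — variants inside an evolutionary annotation (e.g. regions
  that diverged rapidly on the hominin lineage);
* **matched** — variants inside control regions sampled to replicate the
  annotation's genomic covariates (length, chromosome, GC content, distance
  to the nearest gene, coding overlap) without its evolutionary history;
* **background** — everything else.

The association model regresses the phenotype jointly on the three
z-standardized partition scores (plus caller-supplied covariates):

    y ~ β_bg·PGS_bg + β_m·PGS_m + β_a·PGS_a + covariates

The annotation coefficient `β_a` is the headline estimate. Because the
matched term is in the model, a nonzero `β_a` cannot be explained by generic
genomic properties of the annotation's locations; it is specific to the
annotated sequence class. The nested model-improvement test compares the
full model with the model lacking the annotation term (partial F-test for
linear phenotypes, likelihood-ratio χ² for logistic), and `ΔR²` is the
corresponding gain in explained variance. For binary phenotypes `ΔR²` uses
Nagelkerke's pseudo-R², which is stated in the result metadata because the
choice is not canonical. The per-SNP power ratio
`ρ = (ΔR²_annot / n_annot) / (R²_ref / n_ref)` expresses how much more
variance an average annotation SNP carries than an average genome-wide SNP;
with the printed study inputs (ΔR² = 0.040 over 1 763 SNPs vs R² = 0.037
over ~300 000) it evaluates to ≈184. Multiple phenotypes are controlled by
Benjamini–Hochberg step-up FDR.

Scores and quantitative phenotypes are standardized to mean 0, SD 1 before
fitting, so all reported βs are per-SD; results are therefore invariant to
affine rescaling of the inputs (tested).

## Coordinates and the single conversion point

Intervals are BED (0-based, half-open); variant positions are VCF (1-based).
The one conversion rule in the package: a position `p` overlaps `[s, e)` iff
`s < p ≤ e`. Partition labels use precedence annotation > matched >
background and are exhaustive by construction.

## Matched-control sampling

The matcher z-scores the covariates over the candidate pool and performs
greedy nearest-neighbour selection without replacement, within chromosome,
with the target order randomized by the seed and distance ties broken by
candidate file order (deterministic given the seed). The diagnostics report
per-covariate standardized mean differences (SMD = |mean_t − mean_c| /
pooled SD); SMD < 0.1 on every covariate is the test-suite default for an
acceptable match, not a hard failure of the function. The covariate set is
user-extensible (`covariate_columns`). In the permutation-enrichment null,
control sets are re-drawn per permutation as chromosome-stratified random
samples from the pool: a deterministic matcher would re-draw essentially the
same set each time and the null would be degenerate, so matching in the null
is at the stratum level. Enrichment p-values use the add-one form
`(r+1)/(n_perm+1)`, which is never 0 and conservative under the discrete
overlap statistic.

## Summary statistics, clumping, and scoring

Effect alleles are aligned to the genotype alt allele by (chrom, pos) with a
sign flip when the effect allele is the ref allele; strand-ambiguous A/T and
C/G sites are dropped and counted. Relabeling ref/alt at every site shifts
all scores by the constant `−2Σβ` and leaves standardized scores unchanged.
LD clumping is greedy: visit variants by ascending p-value (ties by id, so
results are order-invariant), keep a variant unless its squared dosage
correlation with a kept variant within the window exceeds the threshold.
Defaults r² = 0.1 and window = 250 kb are configurable and logged; no
p-value threshold is applied by default, so the background partition keeps
its genome-wide scale. Monomorphic variants are treated as uncorrelated with
a logged warning. Missing modern dosages are mean-imputed. Degraded
(ancient) genotypes are scored over observed sites and rescaled by total
|β| mass over observed |β| mass, with the coverage fraction reported; the
rescaled score is unbiased for the complete-data score under missingness
independent of genotype (tested by simulation).

## Reversions

A reversion is a rare variant whose alt allele equals the inferred
human–chimpanzee ancestral base while the ref allele does not — i.e. it
undoes a human-specific substitution. "Rare" defaults to cohort alt
frequency < 0.01 (the source analyses say "rare" without printing a cutoff);
the threshold is a parameter. Variants with unknown ancestral state are
excluded from classification rather than treated as non-reversions, to
avoid polarization bias. Burdens count carried alleles (het 1, hom 2) —
configurable to carrier status — within 10 kb flanks of each region class,
each variant at most once per class. Burden–phenotype association is a
regression of the phenotype on the standardized count (logistic for
diagnoses).

## Motif statistics and York regression

PWMs are JASPAR-style count matrices converted to probabilities with a 1e-3
pseudocount; background defaults to uniform 0.25 and can be overridden. The
variant effect `Δs` is the best log2-odds window score of the alt context
minus that of the ref context, over all motif placements covering the
variant on both strands; windows containing N are skipped, and the scan is
reverse-complement invariant (tested). Per motif, the selection statistic is
`x = mean(−Δs | reversions) − mean(−Δs | other rare variants)` with Welch SE
and p: positive `x` means reversions disproportionately destroy predicted
binding, i.e. the derived (hominin) allele gained binding. The language
statistic `y` is the coefficient of the standardized phenotype on the
standardized per-individual motif-integrity burden, defined as the sum over
an individual's rare variants of `−Δs` for that motif. **Both axis
definitions and the burden construction are this package's declared
reconstruction** — the published figures do not print their formulas — and
alternatives can be substituted at the call sites.

York regression fits `y = a + bx` weighting each point by both error
variances (`W_i = w_x w_y / (w_x + b² w_y)`, zero error correlation,
iterated until |Δb| < 1e-10, max 200 iterations). Known limits anchor the
implementation: exact lines give χ² = 0 and the exact slope; σ_x → 0
recovers weighted least squares to six significant digits; with equal
errors the x-on-y slope is the reciprocal of y-on-x. The slope p-value is a
two-sided Wald test. Family enrichment classifies motifs as concordant
(x > 0 and y > 0, both p < α) and builds per-family 2×2 tables with Fisher
exact p, Haldane 0.5 correction only when a cell is zero, and a Wald CI on
log2 OR.

## Balancing-selection diagnostics

The SFS comparison bins minor allele frequencies into (0, 0.1], (0.1, 0.2],
(0.2, 0.3], (0.3, 0.5] — the top bin isolates the intermediate-frequency
(30–50%) range of interest; edges are configurable. Per bin,
`L_k = log2(prop_A / prop_B)` with variant-level bootstrap percentile 95%
CIs (the variant is the resampling unit, implemented as a multinomial draw
over bin memberships, which is exactly equivalent and seed-reproducible).
Bins empty in either set are flagged undefined rather than fatal.
Heterozygosity: per-variant H_obs is the heterozygote fraction among
non-missing calls, H_exp = 2p(1−p); classes are compared by Welch's t on
per-variant H_obs (class sizes differ by orders of magnitude in practice,
and the per-variant unit is this package's documented choice).
`F = 1 − ΣH_obs/ΣH_exp`; negative F is heterozygote excess; all-monomorphic
input is flagged NaN with a warning.

## Ancient trajectories

The "selection coefficient" of a partitioned score is operationalized as
the least-squares slope of the z-standardized score on time in units of
10 000 years toward the present (s > 0 = rising score), with HC1 robust
SEs; genotype coverage may be supplied as a covariate because degraded
calls inflate score noise. The unit is explicit in the result object; no
equivalence to any published ancient-DNA selection estimator is claimed.
Archaic samples are reported as z-scores against a modern reference panel
(n ≥ 30 required).

## Phylogenetic regression

`bm_covariance` builds the Brownian-motion covariance `C[i,j]` = shared
root-to-MRCA branch length (`(d_i + d_j − d_ij)/2` from leaf depths and
patristic distances). PGLS is GLS with `sigma ∝ C` (statsmodels); it reduces
to OLS on a star tree to machine precision and is invariant to rescaling all
branch lengths. The binary-trait model is a quasi-likelihood logistic GEE
whose working residual correlation is `R(α) = exp(−α · d_ij / T)` (T = tree
height), with α selected on a grid — always including α = ∞, where R = I and
the estimator *is* standard logistic regression — by a Gaussian
quasi-likelihood of the Pearson residuals. This is an Ives–Garland-style
construction chosen for desk-scale robustness; numerical equivalence to any
specific published estimator is not claimed, and the star-tree limit is the
correctness anchor. Per-species similarity scores are
`(mean percent identity over annotation regions − mean over background) /
SD over background`, from gap-free columns of pairwise alignments; the
z-normalization is likewise a declared reconstruction with the raw mean
selectable.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical skeleton of the study design:

* genotypes at Hardy–Weinberg inside equicorrelated LD blocks (two latent
  Gaussian haplotypes per individual, threshold at the MAF quantile);
  defaults: 600 variants, 60 blocks of 10, latent correlation 0.2, MAF
  U(0.05, 0.5), two chromosomes;
* whole LD blocks assigned to partitions (10% annotation, 10% matched) so
  partition structure is not diluted by within-block LD; annotation/matched
  BED regions cover their blocks;
* trait heritability concentrated per partition — defaults h²_annot = 0.04
  and h²_bg = 0.037, the study's variance scale — with Gaussian noise
  filling the remainder; realized heritability matches the config within
  ±0.01 at large n (tested);
* GWAS weights estimated in an independent simulated discovery cohort
  (default n = 20 000) by per-variant OLS, with half the rows reported on
  the opposite allele so harmonization is genuinely exercised. Weight noise
  mildly attenuates ΔR̂² below h²_annot (≈0.037–0.039 at defaults);
* rare variants (default 200, MAF < 0.01) placed near annotation/matched
  regions or in the background, with ancestral alleles set so reversions are
  enriched near the annotation (rates 0.5 vs 0.2; 5% unpolarized), and a
  binary disorder driven by the annotation reversion burden (log-odds 0.16
  per SD, prevalence 0.15 — the study's effect scale);
* an ancient panel (3 244 ancient samples spanning 150–18 775 years BP with
  score drift 0.088 SD/10 ka, 10 archaic samples at +0.91 modern SD, 503
  moderns) and a birth–death species tree (170 species, height scaled to 1)
  with Brownian traits: a similarity score, a binary trait thresholded to
  exactly 49 positives on a latent BM + 1.41·similarity, and continuous
  traits with coefficients 0.42 and 0.44.

A single integer seed drives named substreams (genotypes, effects, noise,
discovery, alleles, rare, disorder, tree, traits, alignments, regions), so
identical configs give byte-identical files and components can be varied
independently.

Deliberately absent realism: no recombination maps or coalescent LD decay
(blocks are equicorrelated and independent), no population structure or
relatedness, no genotyping error, no allele-frequency differences between
discovery and target cohorts, no selection acting within the simulation,
and alignments with i.i.d. substitutions. Passing tests therefore
demonstrate that the estimators recover known truth under their stated
assumptions — calibration, additivity, oracle agreement — not that the
pipeline is robust to confounding in real cohorts (ancestry stratification,
cross-population weight portability, assay artifacts).

## Numerical choices and degenerate inputs

Zero-variance partitions (e.g. no annotation SNPs) enter the model as
exact-zero columns rather than failing standardization; perfectly collinear
score terms raise an error naming the terms. Logistic separation and
non-convergence raise. Empty SFS bins flag NaN. York non-convergence raises
with the slope trace. The PGLS covariance receives 1e-10·mean(diag) jitter
before Cholesky so floating-point PSD slack on simulated trees is tolerated
while genuinely singular trees still raise. Working correlations that are
singular at small α are skipped on the α grid. Test and acceptance problem
sizes (500 calibration refits at n = 1000; 200 recovery replicates at
n = 2000; 200-replicate bootstrap-coverage and PGLS checks; 100-replicate
phylogenetic power checks) are the package's desk-scale study conditions,
chosen to make the Monte-Carlo error small relative to each check's
tolerance.

## Known limitations

The x/y motif statistics and similarity normalization are reconstructions
(flagged above). The phylogenetic logistic α is selected on a coarse grid by
a Gaussian criterion, adequate for detection but not for interpreting α
itself. Score-trajectory slopes are descriptive drift rates, not
population-genetic selection coefficients. The matcher is greedy, not
optimal-transport; with pathological pools the SMD report is the guard. The
X chromosome, imputation, and LDpred2-style weight re-estimation are out of
scope.
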