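# Methods

`clineflower` implements a complete mixed-model GWAS workflow for clinal
flowering-time variation in panels of inbred wild accessions, together with a
synthetic-data generator that reproduces the statistical structure such a
study assumes. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic experiments do and
do not demonstrate.

## The synthetic study (`clineflower.simulate`)

**What it emulates.** A panel of ~130 inbred accessions collected along a
latitudinal cline, genotyped at thousands of biallelic SNPs on six
chromosomes plus an unanchored contig group labelled "0", phenotyped as
days-to-first-flower on three replicate plants per accession, with
right-censoring of accessions that have not flowered by 200 days. Flowering
time is driven by a small number of large-effect loci whose allele
frequencies follow the cline, on top of a polygenic background, so that total
genetic variance is high (broad-sense heritability ≈ 0.9) and two causal loci
jointly explain ≈ 0.6 of the single-plant variance.

**Population structure.** Subpopulation allele frequencies follow a
Balding–Nichols draw: for ancestral frequency p and divergence parameter F
(`fst_like_divergence`), each subpopulation's frequency is
Beta(p(1−F)/F, (1−p)(1−F)/F). Under this model the expected Hudson Fst
between two subpopulations equals F, which the test suite verifies against a
textbook Fst computation (±0.05 at 3000 SNPs). Accessions are near-homozygous
(heterozygote rate 0.02 by default) with 2% missing calls; both are
synthetic conveniences, not estimates of any real panel.

**Variance budget.** `target_causal_r2`, `polygenic_h2` and the residual
remainder partition the *single-plant* phenotypic variance
(`total_sd`² = 35² days² by default). Defining the budget at plant scale
makes the replicate-ANOVA broad-sense heritability equal
`target_causal_r2 + polygenic_h2` by construction, while the accession-mean
causal R² becomes r²c / (r²c + h²p + (1−r²c−h²p)/R) ≈ 0.64 for the default
0.6/0.3/0.1 split with R = 3 replicates. Components are orthogonalised
in-sample — the polygenic draw is residualised on the causal dosages, and the
accession-level noise means on both — and scaled to exact sample variances.
Without this, random cross-covariances at n ≈ 130 would make the reported
variance fractions mis-sum by up to ±0.03; with it the fractions in
`TruthRecord` sum to 1 exactly on the accession-mean scale. `residual_sd`
may be set explicitly (days); by default it is derived from the budget.

**Causal architecture.** Causal SNPs are restricted to chromosomes 1–6 with
MAF ≥ 0.1. With `clinal_causal` (default), candidates are ranked by the
gradient of their subpopulation allele frequencies and the causal set is
drawn from the top tercile. Drawing from the *extreme* of the gradient score
would select loci maximally confounded with kinship, which the mixed model
then absorbs — a regime in which no scan can recover the loci and which does
not correspond to a study that did detect its top SNPs. Per-locus effect
magnitudes are drawn uniform(0.8, 1.2) before joint rescaling: comparable
magnitudes with MAF-driven differences give a ~2:1 split of marginal
variance between two loci, matching the reported architecture this design
mirrors (marginal R² ≈ 0.39 vs ≈ 0.18); strongly unequal draws would make
the second locus undetectable at desk-scale sample sizes.

**Day scale and censoring.** Accession values are centred at
`baseline_days + 2·total_sd` (default 60 + 70 = 130 days), so the earliest
accessions flower near the 60-day baseline, the range spans roughly 60–200
days, and a small fraction of accessions exceeds the 200-day censoring
window. Censoring is applied at the accession-mean level per environment;
censored accessions have replicate values masked. Days are floored at 1.

**Latitude** is subpopulation centre (31°–43° N, south to north) plus
uniform ±1.5° jitter. It is metadata for descriptive statistics and maps
only; inference never uses it.

**Two environments.** With `n_environments=2`, a `gxe_fraction` of the
causal loci carries an additional delaying effect in environment 2
(`env_delta_scale` × effect per dose), generating the
genotype-by-environment signal that the ratio phenotype targets.

**What the generator does not emulate:** linkage disequilibrium from shared
recombination history (SNPs are drawn independently given subpopulation
frequencies, so LD arises only from structure), realistic allele-frequency
spectra, selection, non-normal residuals, and environment-specific error
variances. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not performance on any real
panel.

## Marker handling (`clineflower.genio`)

Dosage is the alt-allele count in {0, 1, 2}, NaN for missing; coordinates
are 1-based inclusive in every external format (VCF, BED is converted on
read/write). Multiallelic records are skipped, not split. MAF is
min(p, 1−p) with p = mean non-missing dosage / 2; the MAF ≥ 0.1 filter is
applied after reading and is idempotent. Imputation is deliberately naive:
`mean` (default before association, where real-valued dosages are fine) or
`major` (modal dosage, required wherever an integer domain is needed —
minor-allele counts, genotype classes). Haplotype-model imputation is out of
scope; the naive mode is a documented deviation, adequate at 2% missingness.
The MAF filter is computed on observed calls and applied before imputation;
at 2% missingness the two orderings differ negligibly, and filtering first
keeps the imputed values out of the frequency estimate.

## Phenotype statistics (`clineflower.phenostats`)

Accession means average the non-masked replicates; non-flowered accessions
are dropped by default or assigned an explicit sentinel (250 days) in the
sensitivity mode. Broad-sense heritability uses the one-way random-effects
ANOVA intraclass correlation, H² = σ²_b/(σ²_b + σ²_w) with
σ²_b = max(0, (MSB − MSW)/ñ) and ñ the harmonic-mean replicate count —
the standard unbalanced-data estimator, clipped to [0, 1]; it is invariant
to shifting and positive rescaling of the phenotype. The latitude
correlation is Pearson's r with the two-sided test (the linear-regression
framing of cline plots). k-means on paired condition means runs on raw day
scales (both axes share units) with 10 restarts and a fixed seed.

## Mixed-model scan (`clineflower.amm`)

Model: y = Xβ + u + e with u ~ N(0, σ²_g K), e ~ N(0, σ²_e I). Kinship is
VanRaden's centered cross-product, K = ZZᵀ / Σ 2p̂(1−p̂), the standard choice
in the EMMAX family. Variance components are estimated once by REML on the
null (intercept-only) model via a single eigendecomposition of K and a 1-D
profile over δ = σ²_e/σ²_g: a 100-point grid on log₁₀δ ∈ [−5, 5] refined by
bounded Brent search on the best bracket. Degenerate directions (pure noise,
pure polygenic) drive δ to a boundary and are well behaved.

Each SNP is then tested by GLS with the covariance σ²_g K + σ²_e I held
fixed — the "accelerated" (EMMAX-type) approximation. Implementation:
whiten y, the intercept and all dosage columns by D^{−1/2}Uᵀ (U, D from the
eigendecomposition), then solve every 2-parameter regression in closed form,
re-estimating the residual scale per SNP with n−2 degrees of freedom and
applying a Wald F(1, n−2) test. Re-estimating the scale makes the K = I
limit reduce *exactly* to the classical per-SNP t-test, and the general case
equal an explicit covariance-inversion GLS oracle to 1e−8 (both asserted in
the test suite). The F with n−2 denominator df (rather than χ²₁) was chosen
for small-sample honesty at n ≈ 130. SNPs monomorphic in the tested subset
get p = 1 and a flag instead of being dropped, keeping row alignment across
permutations. Covariates beyond the intercept are accepted by the REML fit
but not used by default. The genomic inflation factor is
λ = median χ²(p)/0.4549.

## Permutation thresholds (`clineflower.permthresh`)

"Randomized data" is implemented as phenotype permutation across accessions —
the standard GWAS choice. Each permutation re-fits the REML components by
default (`refit_reml=False` reuses the observed fit for speed) and re-runs
the full scan; the α-level threshold is the ceiling order statistic
⌈(1−α)·n_perm⌉ of the sorted scan maxima, so thresholds are achieved sample
values and exactly reproducible. Permutations are generated after sorting
accessions by ID, making thresholds invariant to joint reordering of the
inputs. Caveat: permutation breaks the phenotype–kinship link, so under
strong structure the null is slightly conservative; the calibration
experiment in the test suite (no causal loci, 120 accessions, 2000 SNPs,
200 permutations, 200 fresh null scans) checks that the realized family-wise
error at the 5% threshold stays in [0.02, 0.08]. Significance is strict
inequality (−log₁₀p > threshold), which makes the 5% set always a subset of
the 10% set.

## Candidate windows (`clineflower.windows`)

Window = [pos − W, pos + W], W = 10 kbp by default, clipped at 1 and at the
chromosome end when lengths are provided. Any ≥ 1 bp intersection with the
gene body qualifies (promoter vs body is not distinguished; strand is
ignored). The per-gene view merges SNPs sharing a gene and keeps the best
(minimum) p-value. Functional annotation is a pass-through description field
from the annotation file; remote-database annotation is out of scope.

## Variance-explained model (`clineflower.predict`)

"Non-linkage top SNPs" are produced by greedy p-value-ordered pruning:
walk SNPs by ascending p (chromosome "0" excluded), accept one iff its
dosage r² with every accepted SNP is < 0.5, stop at k = 10. This reproduces
"lowest p per linked set" semantics deterministically. Nested OLS models on
the first m selected dosages give the R² curve (non-decreasing by
construction, re-verified against a normal-equations oracle), joint-refit
coefficient p-values, and per-step prediction formulas. A rank-deficient
step is flagged and fit by minimum norm rather than aborting.

The matched permutation null re-fits the same OLS on random SNPs drawn from
chromosomes 1–6 with *exactly* the template's minor-allele count, computed
on major-mode-imputed integer dosages (mean imputation would break exact
matching). Sampling is without replacement within a draw and with
replacement across draws; a template may enter its own null (excluding it
would bias the null small). Empirical p-values use (r+1)/(n+1). Genotype-
class comparisons use the two-sided Wilcoxon rank-sum test between the
homozygote classes, with heterozygotes (rare in inbred panels) summarised
but excluded; classes with fewer than two accessions skip the test with a
warning.

## Problem sizes

The analysis scripts and the acceptance script run the study at 132
accessions × 5000 SNPs with 200-permutation thresholds and 1000-draw matched
nulls; recovery experiments in the test suite use 100–132 accessions,
600–5000 SNPs and 8–50 seeds per property. These sizes were chosen so the
full suite exercises every stage end to end in well under a minute per
property while keeping Monte-Carlo error comfortably inside each asserted
tolerance; conventions (order statistics, seed handling) are size-invariant.

## Known limitations

- No real LD structure: pruning and proxy-recovery behaviour on real panels
  with block LD is not exercised.
- The EMMAX approximation fixes variance components from the null fit; for
  very large effects exact per-SNP REML would differ slightly (not
  implemented as a default path).
- The permutation null ignores phenotype–kinship coupling (conservative
  under strong structure).
- Naive imputation is only adequate at low missingness.
- Censoring is handled by exclusion or a sentinel, not by survival-style
  likelihoods.
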