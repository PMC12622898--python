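# clineflower

Mixed-model genome-wide association analysis of clinal flowering-time
variation in panels of inbred wild accessions — the full workflow from
replicate phenotypes to candidate genes and a top-SNP variance-explained
model, plus a synthetic-data generator so every stage is testable without
any external download.

## The problem

Wild accessions of a long-day plant collected along a latitudinal cline
(think wild *Lotus japonicus* across the Japanese archipelago) vary strongly
in days-to-first-flower, with northern accessions flowering later and some
never flowering within the observation window. Flowering time is highly
heritable but confounded with population structure: allele frequencies and
phenotypes both follow the cline, so a naive per-SNP regression is full of
false positives. The workflow implemented here is the standard answer:

- **Phenotype layer** — replicate plants are averaged per accession;
  accessions that never flower by 200 days are censored (excluded, or
  assigned a 250-day sentinel in a sensitivity mode). Broad-sense
  heritability comes from the one-way ANOVA intraclass correlation
  H² = σ²_b/(σ²_b + σ²_w); cline strength from the Pearson correlation of
  accession means with latitude; paired growth conditions are compared with
  per-accession flowering-time ratios and k-means clustering.
- **Association layer** — y = Xβ + u + e with u ~ N(0, σ²_g K) for a
  VanRaden kinship K. Variance components are REML-estimated once on the
  null model and then fixed for every per-SNP generalized-least-squares
  Wald test (the EMMAX-style "accelerated" mixed model). Family-wise
  significance thresholds at 5%/10% are the empirical quantiles of the
  maximum −log₁₀p over phenotype permutations.
- **Interpretation layer** — genes within ±10 kbp of significant SNPs are
  candidates; the scan's top SNPs are LD-pruned (r² < 0.5), entered into
  nested OLS models to trace the variance-explained curve R²(m), and the
  observed R² is tested against random SNPs matched on the exact
  minor-allele count (MAC), drawn from the anchored chromosomes.

## Worked example

The numbered scripts under `analysis/` run one synthetic study end to end
(132 accessions, 5000 SNPs, two clinal causal loci at joint r² = 0.6, total
genetic variance 0.9, censoring at 200 days):

```sh
python analysis/01_simulate_study.py
python analysis/02_phenotype_statistics.py
python analysis/03_association_scan.py
python analysis/04_permutation_thresholds.py
python analysis/05_candidate_genes.py
python analysis/06_variance_explained.py
```

Output of the phenotype and association steps:

```
131 flowered accessions (of 132); mean flowering 129.4 d, range 53-199 d
broad-sense heritability H2 = 0.907 (simulated genetic fraction 0.90)
latitude correlation r = 0.193 (p = 0.028); northern accessions flower later
...
REML null fit: sigma2_g = 228.6, sigma2_e = 670.7 (ratio 0.25)
genomic inflation lambda = 0.954 (near 1: structure absorbed by the mixed model)
top hit: chr4_7881358 (-log10 p = 12.2); 2/2 true causal loci in the top 5
...
200 permutations: thresholds -log10 p = 4.96 (5%) / 4.54 (10%)
causal loci beyond the 10% threshold: ['chr3_4125526', 'chr4_7881358']
```

and of the variance-explained model:

```
R2 curve: [0.353, 0.636, 0.666, 0.667, 0.7, 0.703, 0.708, 0.708, 0.726, 0.746]
1-SNP model:  days = 112.6 + 20.62*chr4_7881358
2-SNP model:  days = 99.77 + 18.65*chr4_7881358 + 18.55*chr3_4125526
MAC-matched null (top 2, MAC=[103, 99]): 95th pct R2 = 0.065 vs observed
0.637 (empirical p = 0.004)
mean latitude: both-late 40.3 vs both-early 34.6 (late genotypes sit further north)
```

Reading this: the replicate ANOVA recovers the simulated heritability
(0.907 vs 0.9); the mixed model keeps genome-wide inflation at λ ≈ 0.95
despite the cline; both simulated causal loci exceed the permutation
threshold; the first two selected SNPs explain 0.636 of the accession-mean
variance — far beyond the 0.065 that MAC-matched random SNP pairs reach —
and their late alleles sit ~6° further north, the genotype–geography
pattern a clinal architecture produces. Small tables land in `results/`,
large intermediates in `scratch/`.

## Layout

```
src/clineflower/     the library: simulate, genio, phenostats, amm,
                     permthresh, windows, predict
analysis/            numbered narrative drivers over the library
tests/               pytest suite incl. oracle-equivalence and
                     calibration/recovery experiments
scripts/acceptance.py
docs/methods.md
```
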