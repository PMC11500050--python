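# Methods

This note documents the statistical procedures, the defaults and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Meta-analysis

Per-study effects are per-allele log odds ratios. Published rows that
carry only an OR with a 95% CI are converted with
`se = (ln U − ln L)/(2·z₀.₉₇₅)`, `z₀.₉₇₅ = 1.959964` fixed; natural
logarithms throughout. When full-precision betas/SEs are available they
take precedence over OR/CI conversion. Pooling is inverse-variance
fixed effects; heterogeneity is Cochran's Q with k−1 df and
I² = 100·max(0, (Q−df)/Q), defined as 0 when Q = 0 and NA for a single
study. No random-effects model, meta-regression or genomic control is
provided.

**The "Q" column convention.** Published association tables often label
the Cochran-test *tail probability* simply "Q". The bundled 42-variant
example is such a table: recomputing tail probabilities from its
per-study ORs/CIs reproduces the printed column (0.19, 0.01, …) at two
decimals, whereas the raw Q statistic cannot. `MetaResults` exposes
both `q_stat` and `q_p`; the file dialect writes `Q_P`. A heterogeneity
"significant" flag, where needed, uses q_p < 0.05.

**Classification and rounded inputs.** Signal classes are
firm_novel / suggestive / replicated_known / not_significant as defined
in the README, with gates gw = 5×10⁻⁸ and nominal = 0.05.
Two-decimal published ORs/CIs limit the precision of a recomputed meta
p: for variants whose true meta p sits within rounding distance of
5×10⁻⁸ (e.g. a published 4.61×10⁻⁸), the recomputed value can land on
the wrong side of the gate. `run_meta_table` therefore accepts reported
meta p-values for the classification gate when the caller has them (the
bundled table ships its published meta-P column); the pooled estimate,
Q and I² are always recomputed. Without reported values the recomputed
p is used.

**Allele harmonization.** Study-B effects are sign-flipped when the
allele pair is swapped, complement-strand pairs are mapped before the
same/swapped decision, and strand-ambiguous A/T and C/G variants are
skipped unless both effect-allele frequencies are present and agree
within 0.2 for exactly one orientation. Which allele a published study
reported after its own harmonization is generally unknowable from a
table; this flip rule is our convention and skipped variants are
reported, not dropped silently.

## Association scan

Maximum-likelihood logistic regression per variant (dosage +
covariates), Wald z and two-sided p — Wald rather than LRT/score to
match common GWAS output. Monomorphic variants return NA with reason.
On separation or non-convergence the scan falls back (when enabled) to
Firth's bias-reduced penalized likelihood, implemented as Newton
iterations on the Jeffreys-modified score; far from separation it
agrees with the MLE (checked against statsmodels in the tests).

QC order is fixed: sample missingness → variant missingness → MAF →
Hardy–Weinberg in controls only. Defaults (MAF ≥ 0.01, missingness
≤ 0.05, HWE p ≥ 10⁻⁶) are ordinary chip-QC practice. The HWE test is
the exact conditional test on genotype counts (recurrence over
heterozygote counts; validated against an explicit enumeration oracle).
Hard calls for HWE come from rounding dosages.

Principal components are the left singular vectors of the
column-standardized dosage matrix, computed after greedy LD thinning at
r² < 0.2 (threshold our choice; windowed for speed) so local LD does
not dominate the top axes; deterministic up to sign. The default
covariate count in the pipeline is configurable (k = 10 is a common
choice for this design; the examples use what each test states).

## Risk loci

Greedy p-ordered clumping (FUMA behaviour) at r² < 0.6 defines
independent significant SNPs; candidates are any-p SNPs with r² ≥ 0.6
to an is-SNP (boundary inclusive; no additional p filter — configurable
via the threshold arguments); leads re-clump the is-SNPs at r² < 0.1.
Ties in p break by (p, chrom, pos). Per-lead intervals span that lead's
candidates and merge transitively when same-chromosome boundary *gaps*
(not lead distances) are ≤ 250 kb. A candidate claimed by two merged
loci is assigned to the first in (chrom, start) order, so candidates
partition exactly. Intervals are half-open in memory; the BED output is
0-based half-open. The published counts from this design (119 is-SNPs,
51 leads, 4001 candidates, 41 loci) require the full external summary
statistics and a reference LD panel; only the procedure, verified
against brute-force oracles, is in scope here.

## Polygenic risk scores

Clumping uses the greedy p-ordered rule with window 250 kb and r² 0.1
by default (the published analysis's exact PRSice parameters are not in
its main text; these are explicit, configurable defaults). Scores are
weighted dosage *sums*; the sum-vs-average choice does not affect
rank-based metrics or the logistic fit. "PRS-R²" is the Nagelkerke
pseudo-R² of phenotype ~ score + covariates minus that of
phenotype ~ covariates, both against the intercept-only null. The
default cutoff grid is {5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1};
`fine_grid()` offers PRSice-like 5×10⁻⁵ steps.

The permutation p re-runs the *entire* cutoff search on each of B
permuted phenotypes, so the selection optimism of the grid search is
inside the null; `perm_p = (1 + #{perm ≥ observed})/(B + 1)` has floor
1/(B+1), attained exactly when no permutation ties or beats the
observed fit — with B = 1000 the floor is 9.99×10⁻⁴. Per-cutoff scores
are precomputed once (they do not depend on the phenotype); the inner
logistic fits use a small Newton-IRLS routine cross-checked against
statsmodels. AUC is the Mann–Whitney statistic with half credit for
ties; its CI uses DeLong's placement-value variance. Group means are
compared with Welch's t-test.

The published headline numbers (AUC 0.713, PRS-R² 0.126, 34,832 SNPs at
p < 3.98×10⁻²) require the real cohort genotypes and the full external
summary statistics and are not reproducible at desk scale; the package
instead verifies the qualitative finding (the best-fitting cutoff beats
the genome-wide-only model) and calibration properties on synthetic
data.

## Prioritization ledger

Scores and tiers are exactly the partitions documented in the README;
aggregation over a gene's SNPs is best-evidence per criterion (max
CADD/pLI, lowest RegulomeDB category, OR over flags, most severe
consequence), which is the natural reading of "any associated SNP
with CADD ≥ 10". RegulomeDB sub-categories map by leading digit. The
non-coding track applies the same CADD/pLI cutoffs as the coding track.
A gene scored on both tracks reports both scores; the pipeline-level
tier is the better track tier by default (`either`), with `both`
available since the reconciliation rule for dual-track genes is not
externally fixed. Gene-set enrichment is the one-sided hypergeometric
upper tail.

## Network and drugs

Edge enrichment counts induced-subgraph edges against B equal-size node
sets drawn uniformly from the network universe (degree-stratified
drawing available); uniform resampling is a deliberate simplification
of database-style analytic backgrounds, so its expected-edge value
plays the role of, but does not reproduce, such formulas. The drug join
restricts to tier-1/2 target genes, deduplicates by (drug, gene) and
reports counts per regulatory status before the approved-only filter.

## Synthetic data

Genotypes: within blocks of adjacent variants, latent haplotype values
are multivariate normal with AR(1) correlation ρ^|i−j|; each haplotype
thresholds at the allele-frequency quantile and the two indicators sum
to the dosage. This Gaussian-copula construction was chosen over
coalescent simulation for speed and direct control of block LD; it has
no recombination-map realism, no population structure (beyond an
explicit two-subpopulation mode used in the PCA tests) and no
genotyping error, so passing tests demonstrate algorithmic correctness
and statistical calibration, not robustness to real-data artefacts.
Defaults: 1116 samples with an expected 133/983 case-control split
(intercept ln(133/983)), MAF uniform on [0.05, 0.5], blocks of 10 at
ρ = 0.6.

Phenotypes are Bernoulli with P(case) = logistic(intercept + Σ βⱼdⱼ);
`center=True` mean-centers dosages inside the sum so the intercept
alone sets the expected case fraction (used whenever effects are
planted).

Two-cohort designs return a genotyped cohort A and directly generated
cohort-B summary statistics: β_B = shared + N(0, heterogeneity_sd²),
SE fixed at `cohort_b_se` (default 0.03, matching the CI widths a
~10⁵-sample study prints at common MAF), p from the Wald z. No
sampling-noise term is added on the B side, so planted gray-zone
z-scores are exact there. One consequence worth stating: for null SNPs
the meta Q is ≈ χ²₁·se_A²/(se_A²+se_B²), so when cohort B dominates
precision the long-run *mean* null I² is ≈ 15% even though the
*median* is 0 — a property of the I² estimator, not a bug; the tests
assert the median and a mean bound accordingly.

`gray_zone_config` plants two common variants (MAF pinned at 0.45) with
log-OR 0.42 and a cohort-B z of 5.2: expected replication-cohort p
≈ 1.4×10⁻³ (nominal, far from genome-wide) and cohort-B p ≈ 2×10⁻⁷
(gray zone), so pooling is expected to push both past 5×10⁻⁸ — the
rescue pattern the design exists to detect. With honest sampling noise
in the replication cohort the per-replicate probability that *both*
variants clear both gates is ≈ 0.8, so the end-to-end test asserts a
majority of replicates, not near-certainty.

Annotation and drug generators draw evidence spanning all tiers and
attach ground-truth scores; the test suite re-derives the truth with an
independently written straight-line scorer.

## Problem sizes used in the checks

Meta oracle equivalence: 1000 random 2–5-study instances at 10⁻¹⁰
tolerance. Locus oracles: 100 random instances up to 200 SNPs.
Permutation floor: 2000 SNPs × 1000 samples, B = 1000. PRS properties:
25 effect + 25 null replicates at 300 SNPs × 800 samples. Association
calibration: 100 replicates per effect size at n = 2000 and a
1000-variant null scan. These sizes make the full suite run in well
under a minute while leaving each check's Monte-Carlo error far from
its assertion margin.

## Known limitations

No genotype imputation, liftover, indel normalization, bgen/pgen
support, X chromosome, mixed models, LD-aware shrinkage PRS, tissue
expression analysis or external-database retrieval: annotation values
(CADD, pLI, ncRVIS, RegulomeDB), interaction networks and drug-target
tables arrive as input files. The edge-enrichment null is resampling,
not an analytic background. Classification treats the two studies
asymmetrically by design (replication vs published) and assumes their
p-values are comparable two-sided Wald probabilities.
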