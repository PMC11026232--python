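# Methods

## Study design being modelled

The pipeline implements a case-control pharmacogenetic analysis of regular
triptan usage in cluster headache. Usage stands in for response: patients
who regularly use sumatriptan injections, sumatriptan nasal spray or
zolmitriptan nasal spray are *users* (controls); patients using no triptan
in any form — including those who tried triptans without effect, and
ergotamine users — are *non-users* (cases); patients using triptan tablets
only are excluded from analysis because tablets are too slow-acting to be a
meaningful CH abortive. Five loci are analysed: four biallelic SNPs
genotyped as such, and the 5-HTTLPR promoter indel with its embedded
rs25531 SNP, handled as a tri-allelic system {L_A, L_G, S} and recoded two
ways (bi-allelic L/S by presence of the 43 bp insertion; collapsed
L_A vs L_G+S because L_G expresses at near-S levels).

## RFLP calling

BcnI digestion yields per-allele fragments L_A {341}, L_G {174, 167},
S {298}, plus constant 126 and 62 bp fragments from every allele. Because
all lengths are distinct and co-migrating duplicates merge on a gel, the
expected *band* pattern of a diploid genotype is the set union of its
alleles' fragments; the six genotype patterns are pairwise distinct
(asserted at import). Calling matches each observed band to expected bands
within a relative tolerance (default ±4%, roughly agarose resolution);
a genotype is called when it is the unique genotype whose pattern is fully
covered and which explains every observed band. The 174/167 pair is treated
as a doublet that may appear as a single band satisfying both. Lanes
missing the constant bands (failed digestion) or containing unexplained
bands are no-calls with diagnostic flags. One special case is a first-class
outcome: an L_G/S pattern with an extra 341 bp band is called L_G/S flagged
`sequencing_required`, and such calls are not usable until confirmed —
mirroring the wet-lab practice of sending those samples to Sanger
sequencing.

## Association statistics

Allele counting excludes tablet-only individuals and missing genotypes;
each called genotype contributes two alleles; group percentages are
rounded half-up to one decimal, the convention of the published tables.
The effect allele defaults to the pooled minor allele, which reproduces
the direction of every published OR.

The logistic engine is an in-package Newton/IRLS maximum-likelihood fitter
(max 50 iterations, convergence when the log-likelihood improves by
< 1e-10, step-halving on overshoot). Separation is detected two ways: a
diverging coefficient norm (> 1e4) during iteration, or a converged
log-likelihood within 1e-8·n of zero (perfect prediction, MLE at
infinity). Wald standard errors come from the inverse observed information;
the genotypic model adds a likelihood-ratio block test against the nested
covariate-only fit. The additive model codes effect-allele dosage 0/1/2
with sex (male = 1) as default covariate and non-user as outcome 1.
Wald p-values are reported (the likelihood-ratio p is exposed for the
genotypic block).

Hardy-Weinberg: biallelic variants use the exact conditional test — the
probability, given the allele counts, of all heterozygote counts no more
probable than the observed one. The tri-allelic system uses a seeded
Monte-Carlo permutation of the allele pool with a Pearson chi-square
statistic and the add-one p estimate (1 + #{perm ≥ obs})/(1 + N).
Crude allelic odds ratios use the 2×2 cross-product with a
Haldane-Anscombe +0.5 on zero cells (flagged) and a log-scale Wald CI;
they serve as a validation cross-check of the adjusted ORs, expected to
agree only approximately. Bonferroni correction multiplies by m = 5 — the
number of variants tested, with the bi- and tri-allelic 5-HTTLPR analyses
sharing one slot — and renders values above 1 as "> 1.0".

## Effector score

Per variant the effector allele is the allele with the higher *relative*
frequency in non-users than in users (it need not be the majority allele
anywhere: rs5443's T is effector at 29.0% vs 28.9%). Exact ties are an
error unless an explicit override resolves them; overrides are tagged, as
the study did for rs6724624 where the in-cohort direction (C) contradicted
the migraine literature (G). 5-HTTLPR's effector is fixed at S by the
bi-allelic rule rather than re-derived per cohort; the tri-allelic detail
is deliberately discarded for scoring. The score is the unweighted sum of
effector copies over the five variants (0–10); individuals missing any
genotype are excluded. The score regression uses the shared IRLS engine
with outcome non-user, male = 1 and age in years, uncentered — the scale
on which the reference estimates (0.204 per allele, −0.483 male, 0.031 per
year) are reported. Identifying effectors in the analysis cohort itself is
in-sample circularity; the API accepts an externally supplied
specification for unbiased use.

## Clinical comparison

Survey answers are kept raw (a list of ticked categories); where several
boxes were ticked for an ordered question the most severe answer — the
maximum under the question's declared category order — is kept, a rule
that is idempotent and order-invariant. Missing answers are excluded from
percentages and tests. 2×2 tables use Pearson chi-square with Yates
continuity correction; larger tables the uncorrected statistic with
df = (r−1)(c−1); an expected count of zero is an error and expected counts
below 5 set a warning flag. Numeric comparisons use the two-sample
Wilcoxon rank-sum test: exact null distribution when the combined sample
is ≤ 50 without ties, otherwise the continuity-corrected normal
approximation (both via scipy). Summary tables report mean ± SD (n−1
denominator) and % (n) excluding missing, with a tablet-only column.

## Power

For an allelic case-control comparison the control frequency p₀ and an
odds ratio imply the case frequency p₁ = OR·p₀ / (1 + p₀(OR − 1)). Power
of the uncorrected two-proportion chi-square test is computed either
exactly — enumerating the two binomial count distributions against the
precomputed rejection region, which is also what a simulation of the test
estimates — or by the classical normal approximation with unequal group
sizes, which satisfies power(OR = 1) = α identically. The detectable-OR
solver bisects log-OR on each side of 1 until the power at the bound is
within 1e-6 of the target. The sampling unit defaults to the individual
(one observation per subject, the convention of the PS sample-size
program, which reproduces the published 80%-power intervals for this
cohort's 109:409 split to within a few percent at European reference-panel
allele frequencies); per-allele counting (2 per subject) is an option.
The reference MAFs shipped (0.42, 0.16, 0.31, 0.43, 0.43) are rounded
European panel values; the published intervals are reproduced within
±10%, not exactly, since the original MAF inputs and program internals
are not recoverable.

## Synthetic cohort generator

The generator draws, per individual: sex (male fraction 0.656), age from a
normal(50.3, 14.3²) truncated to [18, 90], genotypes as i.i.d. allele
pairs (Hardy-Weinberg) at the pooled user+non-user allele frequencies of
the genotyped cohort — for the tri-allelic system L_G's frequency is the
only derivable estimate, (bi-allelic L) − (tri-allelic L_A) — then
tablet-only membership (27/545), and usage from the logistic model
logit P(non-user) = β₀ + 0.204·score + (−0.483)·male + 0.031·(age − mean),
where the score is the individual's true effector count. The intercept is
solved numerically (exact score distribution by convolution, quadrature
over the truncated age density) so the marginal non-user fraction among
non-tablet individuals is 109/518. Age is centred in the *generator* so
the intercept has a clean interpretation; the fitted regression uses
uncentred years, which affects only the fitted intercept. Clinical answers
come from group-conditional category probabilities set to the published
table percentages, with a 5% multiple-answer rate on the ordered questions
(the published report says multiple ticks occurred but not how often) and
~3% item non-response, MCAR; genotype missingness is independent per
variant at rates matching the reported call rates (2%; 2.4% for the RFLP
assay). One root seed spawns eight fixed-order substreams, making cohorts
byte-identical across regenerations.

What the generator does *not* emulate: linkage disequilibrium between loci
(the real loci sit on different chromosomes or far apart), population
structure, informative missingness, and correlations among clinical
answers beyond their common dependence on usage group. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated generating model, not robustness to those real-data features.

## Numerical and design choices

- Problem sizes in the tests are chosen to keep the full suite under half
  a minute: the coverage study uses 500 replicates of n = 2000; the
  recovery study 200 replicates of n = 489 (the complete-case count of the
  reference cohort, generated without missingness or tablet-only
  individuals so the fitted n is exactly 489).
- At n = 489 the logistic MLE of the score coefficient carries the usual
  small-sample bias away from zero (≈ +4% here), so the mean estimate over
  replicates sits slightly above the generating 0.204; the recovery test
  bounds the gap by Monte-Carlo error rather than asserting equality.
- The brute-force oracles (likelihood grid search, exact rational HWE
  enumeration, rank-permutation Wilcoxon, simulated chi-square power)
  live in the test suite and share no code with the implementations they
  check. Full permutation of a 30+30 Wilcoxon is combinatorially
  infeasible, so enumeration checks cap at n ≤ 12 per the exact-method
  regime.
- Ties in effector identification, zero cells in crude ORs, empty groups
  in percentage tables and structural zeros in contingency tables are all
  explicit, flagged or raising conditions rather than silent defaults.
- VCF export covers only the four biallelic SNPs; a tri-allelic indel
  system has no faithful single-record SNP representation, and its
  analysis-ready recodings live in the genotype TSV. Coordinates in the
  VCF are ordering-preserving placeholders, not genome-build positions.
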