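# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `t2dclust`, and what the test suite does and does not
establish about behaviour on real data.

## Overview

The package implements a pipeline for resolving type 2 diabetes (T2D) into
genetic subtypes from multi-ancestry GWAS summary statistics, and for
carrying those subtypes into individual-level analyses:

1. build a risk-allele-aligned matrix of standardized z-scores for
   T2D-associated variants against many cardiometabolic traits;
2. soft-cluster it with Bayesian non-negative matrix factorization under an
   automatic-relevance-determination (ARD) prior, which learns the number
   of clusters K;
3. score individuals with partitioned polygenic scores (pPS) — weighted
   risk-allele dosage sums restricted to one cluster's variants;
4. associate pPS with phenotypes (linear/logistic regression,
   sex-stratified and interaction models, DerSimonian–Laird random-effects
   meta-analysis across cohorts);
5. test clusters for enrichment in cell-type regulatory annotations via
   Wakefield credible sets and a permutation test on cumulative posterior
   probability (cPPA);
6. compute ancestry-equivalent BMI thresholds for T2D risk before and
   after pPS adjustment.

## Matrix construction

Variant selection takes the union of variants reaching `p_threshold`
(default 5×10⁻⁸; 5×10⁻⁶ intended for ancestry-specific runs with less
powerful GWAS) in any input T2D study, then removes indels, the extended
MHC region (default chr6:25–34 Mb, 1-based inclusive — a conventional
window, configurable), variants absent from or weak in the anchor study
(anchor p > 0.05), and variants whose positive-beta risk allele disagrees
between a significant source study and the anchor. LD pruning runs greedily
once per population reference panel (r² < 0.05; variants below MAF 0.001 in
a panel are excluded in that panel) and keeps only variants independent in
every panel. Within a correlated pair the variant with the smaller anchor p
survives: greedy order is anchor p ascending, then genomic position, which
makes the five prunes deterministic.

Strand-ambiguous (A/T, C/G), multi-allelic, or high-missingness variants
(absent from > 20% of trait studies, configurable) are replaced by the best
proxy with r² > 0.8 across panels, or dropped. Traits are removed when
their median sample size is below 5,000 or their minimum p across the final
M variants exceeds 0.05/M; among trait pairs with |Pearson R| > 0.80
(computed on pairwise-complete cells), the trait with the larger maximum
absolute association survives, iterating from the highest correlation down.

Cell values are z = beta/se aligned to the anchor risk allele. Missing
cells take the aligned z of the best observed proxy with r² > 0.5, else the
trait's median observed z, with per-cell provenance recorded. Each trait
column is then centered and scaled to unit variance; the parameters sit in
`scaling_meta` so an alternative scaling can be swapped in without touching
the rest of the pipeline.

## bNMF with ARD

The signed matrix is split into non-negative paired columns (trait⁺ holds
max(z, 0), trait⁻ holds max(−z, 0)), so a cluster can load on a trait in
either direction. The factorization model is a Gaussian likelihood
X ≈ WH with exponential (L1) priors on the columns of W and rows of H that
share one relevance scale λ_k per component, and an inverse-gamma
hyperprior (shape a = 10; scale b set from the data mean as
√((a−1)(a−2)·mean(X)/K₀)). MAP estimation uses multiplicative
majorization-minimization updates for W and H and closed-form updates for
λ_k and the noise variance σ², so the objective is non-increasing — the
suite asserts this numerically. σ² is floored at 1% of mean(X²): when an
exact factorization exists, an unfloored σ² collapses to zero, the ARD
penalty becomes negligible, and redundant components are never pruned. A
component is removed when its column-plus-row mass falls below 10⁻¹⁰ of the
initial total mass.

K is chosen by majority vote over random restarts (default 100; tests and
the acceptance script use 10, which is sufficient at the synthetic problem
sizes); among restarts converging to the modal K the lowest objective wins,
with ties broken by restart seed, and a modal tie goes to the smaller K.
Cluster membership uses a fixed weight threshold, default 0.7802 — a
signal-to-noise-optimal cutoff established in prior cluster work and
carried here as configuration, not re-derived. The threshold applies to W
and H on the same scale, which is the scale of the fit on the standardized
input matrix.

## Partitioned polygenic scores

Individual-level pPS are Σ w·dosage over a cluster's above-threshold
variants, with dosages flipped (2−d) when the counted allele is not the
risk allele and missing dosages imputed as twice the cohort risk-allele
frequency (logged per individual). Standardized scores are z-scored over
the full pooled cohort so that all downstream effects are per SD of pPS on
one common scale across ancestry groups.

The summary-statistic analogue (GWAS-pPS) pools the cluster variants' trait
effects by inverse-variance-weighted fixed-effects meta-analysis. By
default the cluster enters only through variant selection; a configuration
flag additionally multiplies each variant's effect and SE by its cluster
weight for sensitivity analysis, since the two readings of
"weighting by effect size" are both defensible.

## Association analyses

Controls younger than 30 or with any HbA1c ≥ 6.5% are excluded from the
case/control phenotype. For individuals on lipid-lowering medication, total
cholesterol is divided by 0.8, LDL by 0.7, triglycerides by 0.85; HDL is
not adjusted. BMI and triglycerides are log-transformed by default; the
transform list is configuration because the full set of skewed traits is
data-dependent. Continuous outcomes are standardized on the analysis sample
after exclusions and adjustments; binary outcomes use logistic regression
and report log-OR (and OR) per SD of pPS. Default covariates are age, sex,
and genetic ancestry group encoded as categorical indicators (top PCs can
be substituted); binary outcomes with fewer than 500 cases (or controls)
in a cohort are skipped with a reason rather than fitted. Sex interaction
is tested with a sex × pPS term in the pooled model, alongside per-sex
stratified fits. Cohort results pool by DerSimonian–Laird random effects;
non-converged fits are excluded rather than imputed. Discovery outcomes use
a Bonferroni level of 0.05/(K·N); validation traits that fed the clustering
are flagged and left uncorrected.

Ancestry labels come from a random-forest classifier (500 trees, 10 PCs,
fixed seed) trained on labeled reference PC coordinates; individuals whose
maximum group probability is below 50% remain unclassified, and groups with
fewer than 500 classified members are excluded from downstream analyses.
MID is retained as a possible label and the size rule decides its fate.

## Credible sets and enrichment

Wakefield's approximate Bayes factor uses prior SD 0.2 on the effect-size
scale (configurable; the appropriate value depends on the trait scale).
Candidates for a locus are the variants within a 500 kb index-centered
window (read as ±250 kb; a ±500 kb mode exists) with r² ≥ 0.1 to the index.
PPAs are aBFs normalized over the full candidate set, and the credible set
is the smallest PPA-descending prefix reaching 0.99 cumulative mass;
renormalizing after truncation is available behind a flag because the
order of operations is genuinely ambiguous. cPPA for a cluster × annotation
pair sums retained PPAs of variants falling inside the annotation.

The permutation null shuffles locus→cluster assignments jointly with
annotation→cell-type labels, holding locus geometry and interval geometry
fixed; the scheme is isolated behind the permutation routine so
alternatives can be substituted. p = (1 + #{permuted ≥ observed})/(1 +
n_perm) (never exactly zero), with Benjamini–Hochberg q-values across all
cluster × cell-type pairs and significance flags at q < 0.1 and q < 0.001.
Default 10,000 permutations; the calibration tests use 500, which is ample
for the q < 0.1 flag at the test's effect sizes.

## Ancestry-equivalent BMI thresholds

A logistic model of T2D status on log(BMI), age, sex, and ancestry-group
indicators (plus standardized pPS when adjusting) defines each group's risk
curve. The reference risk is the mean predicted probability over the
reference group's individuals with BMI set to the reference value
(g-computation; a covariate-means mode exists behind a flag). The
equivalent BMI solves for equal mean predicted probability in the target
group by a monotone one-dimensional root search in log BMI — uniqueness is
guaranteed by the positive log-BMI coefficient, which is asserted. Root
bounds default to one third through eight thirds of the reference BMI
(10–80 kg/m² at the usual reference of 30), which keeps thresholds
equivariant under a change of BMI units.

In a pPS-adjusted model the pPS covariates are held at the cohort grand
mean for every group when predicting. This is deliberate: the adjusted
comparison asks what the risk gap would be at equal genetic background, so
the score must be equalized across groups. Averaging each group's own
observed pPS distribution instead (available as `pps_reference=
"group_observed"`) leaves any score-mediated risk difference in the
comparison, and the adjustment then cannot move the threshold by
construction. Confidence intervals are nonparametric percentile bootstrap
over individuals (default 500 resamples, refitting the model each time).
The gap-reduction summary is 100·(adjusted − unadjusted)/(reference −
unadjusted), reported raw and rounded to the nearest 5 points.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with known ground truth:

* **Summary statistics.** Z = S∘(W_true·H_true) + Gaussian noise, with a
  fixed ±1 sign per trait so increased/decreased trait splits are
  meaningful; per-study beta = z/√n, se = 1/√n, p = 2Φ(−|z|). Defaults
  plant disjoint variant/trait memberships with member loadings chosen so
  that typical signal cells have |z| ≈ 5–8 (the genome-wide-significant
  regime) and fitted variant weights land near 1.1, comfortably above the
  0.7802 membership threshold; noise defaults to 10% of the mean signal.
  The anchor T2D study places planted variants at |z| between 6 and 12.
* **LD panels.** Exact block-diagonal r² (within-block pairs share one
  value, across blocks zero) with uniform population-specific MAF; no LD
  decay with distance. A designated pair can exceed the pruning threshold
  in exactly one panel to exercise the all-panels rule.
* **Cohorts.** Dosages are Binomial(2, f) under Hardy–Weinberg with
  ancestry-specific frequencies shifted so each group's mean cluster pPS
  moves by the stated number of SDs; T2D follows a logistic model in
  log-BMI (coefficient 4.0, chosen to give a realistic risk gradient across
  the observed BMI range), per-SD pPS effects, and optional ancestry
  offsets; labs are unit-SD values around a positive offset (arbitrary
  units); PCs are linearly separable by ancestry. No admixture,
  relatedness, genotyping error, or realistic phenotype covariance.
* **Annotations.** Background intervals cover a random fraction of variant
  positions; enriched (cluster, cell type) pairs additionally cover that
  cluster's causal variants exactly.

Because planted traits within a cluster are exactly collinear (low-rank
signal), the |R| > 0.80 trait filter correctly collapses them to one trait
per cluster when the full pipeline runs end to end; pipeline-level tests
either accept that or relax the ceiling, and clustering recovery is tested
on the z-matrix directly. Passing tests therefore establish internal
consistency and statistical calibration under these idealized conditions —
they do not establish robustness to real LD structure, assortative
missingness, phenotype measurement error, or population substructure
beyond label-level ancestry.

## Problem sizes and test design

The recovery and calibration suites use sizes chosen to make the targeted
property measurable with stable margins: cluster-count recovery on
200 × 40 matrices over 10 restarts × 10 seeds for K ∈ {2, 3, 4}; enrichment
calibration from ~100 independent null replicates of 20 loci at 500
permutations, with planted-pair sensitivity over 10 seeds; regression
calibration from 1,000 null fits at n = 800 and effect recovery at
n = 20,000; BMI-threshold recovery on two-group cohorts of n = 40,000 with
500 bootstrap resamples. `scripts/acceptance.py` re-runs the same
computations from scratch and writes the resulting rates and estimates as
JSON.

## Known limitations

* The ARD hyperparameters (a = 10, data-driven b) and the σ² floor are
  sensible defaults validated on synthetic structure, not tuned to any
  real matrix; very weak clusters near the noise floor may be pruned.
* The 0.7802 membership threshold is inherited configuration; its
  optimality is scale-dependent and not re-derived here.
* Single-causal-variant aBF fine-mapping ignores LD between credible-set
  members; cPPA inherits that approximation.
* Ancestry-equivalent thresholds describe prevalent-risk equivalence under
  the fitted logistic model; they are not incidence-based and inherit any
  model misspecification in the log-BMI term.
* The GWAS-pPS weighting ambiguity is resolved by a documented default and
  a sensitivity flag rather than empirically.
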