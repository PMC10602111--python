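# t2dclust

Multi-ancestry genetic subtyping of type 2 diabetes (T2D) from GWAS
summary statistics, and downstream analyses of the resulting subtypes in
individual-level cohorts.

Type 2 diabetes is heterogeneous: different people reach hyperglycemia
through different mixes of beta-cell failure, obesity, lipodystrophy-like
fat distribution, and other mechanisms. This package identifies such
mechanisms as *soft clusters* of T2D risk variants. It is aimed at
statistical geneticists who have T2D and cardiometabolic-trait GWAS
summary statistics, LD reference panels, and (optionally) biobank-style
individual-level data, and who want a tested, scriptable implementation of
the whole chain from summary statistics to ancestry-aware clinical
interpretation.

## What it computes

**Variant–trait matrix.** From many T2D GWAS across ancestries, the
pipeline selects genome-wide-significant variants (P < 5×10⁻⁸), removes
indels and the MHC region, LD-prunes against every population's reference
panel at r² < 0.05 (keeping only variants independent in all panels),
swaps strand-ambiguous or poorly covered variants for proxies (r² > 0.8),
and verifies risk alleles against the largest multi-ancestry anchor study.
Trait GWAS are filtered by sample size (median N ≥ 5,000), Bonferroni
significance over the final variants, and mutual correlation (|R| ≤ 0.80).
The result is a matrix of risk-allele-aligned, standardized z-scores.

**bNMF clustering.** The signed matrix is split into non-negative
trait⁺/trait⁻ columns and factorized as X ≈ WH under a Gaussian likelihood
with per-component automatic-relevance-determination priors, so the number
of clusters K is learned: superfluous components shrink and are pruned.
K is selected by majority vote over random restarts; cluster membership is
a weight above 0.7802 (a signal-to-noise-optimal threshold carried as
configuration).

**Partitioned polygenic scores (pPS).** Per individual and cluster,
pPS_k = Σ_v w_kv · dosage_v over the cluster's variants, standardized to
SD units; or, from summary statistics alone, inverse-variance-weighted
fixed-effects pooling of the cluster variants' trait effects.

**Associations.** Linear/logistic regressions of phenotypes on pPS per SD
(with case/control hygiene rules, lipid-medication adjustment, log
transforms), sex-stratified and sex-interaction models, DerSimonian–Laird
random-effects meta-analysis across cohorts, and Bonferroni control
0.05/(K·N) for discovery outcomes.

**Regulatory enrichment.** Wakefield approximate Bayes factors build 99%
credible sets per locus (±250 kb, r² ≥ 0.1 with the index); per cluster and
cell-type annotation, the cumulative posterior probability (cPPA) of
credible variants in the annotation is tested against a permutation null
(10,000 permutations, one-tailed, Benjamini–Hochberg FDR).

**Ancestry-equivalent BMI thresholds.** A logistic model of T2D on
log(BMI), age, sex, and ancestry yields, for each ancestry group, the BMI
at which its predicted T2D risk equals a reference group's risk at a
reference BMI (default EUR at 30 kg/m²), with bootstrap CIs — before and
after adjusting for cluster pPS, plus the percentage of the threshold gap
the adjustment explains.

A synthetic-data module generates all inputs with planted ground truth
(factor structure, LD blocks, ancestry-specific allele frequencies, cohort
effect sizes, enriched annotations) for parameter-recovery testing.

## Worked example

Plant three clusters, recover them, and measure how much of an
ancestry-specific BMI-risk gap the cluster scores explain:

```python
import numpy as np
import pandas as pd

from t2dclust.synthetic_data import (
    make_planted_truth, generate_summary_stats, generate_cohort)
from t2dclust.bnmf import split_nonnegative, fit_bnmf
from t2dclust.pps import individual_pps
from t2dclust.bmi_thresholds import fit_risk_model, equivalent_bmi, gap_reduction

truth = make_planted_truth(K_true=3, n_variants=90, n_traits=24, seed=11,
                           t2d_logor=np.array([0.4, 0.1, 0.1]),
                           ancestry_pps_shift={"EAS": np.array([1.0, 0.0, 0.0])})
studies = generate_summary_stats(truth)
z = pd.DataFrame(
    np.array([[s.z for s in st.stats] for st in studies.trait_studies]).T,
    index=[v.vid for v in truth.variants],
    columns=[st.label for st in studies.trait_studies])

sol = fit_bnmf(split_nonnegative(z), k_max=8, n_restarts=10, seed=0)
print(f"selected K = {sol.K}")
print(f"cluster1 variants above 0.7802: {len(sol.variant_members('cluster1'))}")

cohort = generate_cohort(truth, n=20_000,
                         ancestry_mix={"EUR": 0.5, "EAS": 0.5}, seed=3)
scores = individual_pps(cohort, sol)
eas = cohort.samples["ancestry_label"] == "EAS"
for c in scores.clusters:
    shift = (scores.standardized.loc[eas, c].mean()
             - scores.standardized.loc[~eas, c].mean())
    print(f"{c}: EAS - EUR mean pPS = {shift:+.2f} SD")

unadj = fit_risk_model(cohort.samples)
r_u = equivalent_bmi(unadj, "EAS", "EUR", reference_bmi=30.0, n_boot=0)
adj = fit_risk_model(cohort.samples, adjust_pps=("cluster1",), scores=scores)
r_a = equivalent_bmi(adj, "EAS", "EUR", reference_bmi=30.0, n_boot=200, seed=2)
raw, rounded = gap_reduction(r_u, r_a)
print(f"EAS-equivalent BMI: unadjusted {r_u.equivalent_bmi:.1f}, "
      f"adjusted {r_a.equivalent_bmi:.1f} (95% CI {r_a.ci[0]:.1f}-{r_a.ci[1]:.1f})")
print(f"gap reduction: {raw:.0f}% (rounded to nearest 5: {rounded:.0f}%)")
```

Output:

```
selected K = 3
cluster1 variants above 0.7802: 30
cluster1: EAS - EUR mean pPS = +0.89 SD
cluster2: EAS - EUR mean pPS = +0.00 SD
cluster3: EAS - EUR mean pPS = +0.04 SD
EAS-equivalent BMI: unadjusted 27.2, adjusted 29.7 (95% CI 29.1-30.7)
gap reduction: 90% (rounded to nearest 5: 90%)
```

Reading it: bNMF recovers the three planted clusters and all 30 cluster-1
variants. The simulated East Asian group carries +0.89 SD of the
risk-raising cluster-1 score, so it reaches the European group's 30-kg/m²
T2D risk already at BMI 27.2; holding cluster-1 pPS equal across groups
moves the equivalent threshold back to 29.7, i.e. the score explains ~90%
of the gap (the truth here is full mediation, so 100% up to sampling
noise).

## Command line

Each pipeline stage is also a subcommand of the `t2dclust` console script:
`simulate`, `build-matrix`, `cluster`, `pps`, `associate`, `enrich`,
`bmi-thresholds`, `compare`. All inputs and outputs are delimited text;
`build-matrix` is driven by a YAML config listing the study files, panels,
and any threshold overrides. Example:

```bash
t2dclust simulate --out data/ --seed 3 --k-true 3
t2dclust build-matrix --config data/cfg.yaml --out run/matrix
t2dclust cluster --matrix run/matrix.matrix.tsv --restarts 20 --seed 1 --out run/sol
t2dclust pps --cohort data/cohort --solution run/sol --out run/scores
```

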