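"""Synthetic inputs with planted structure for the whole pipeline.

The generators emulate the statistical structure the analysis assumes:

* variant-by-trait z-score matrices arising from a non-negative factorization
  ``W_true @ H_true`` with a fixed per-trait sign pattern plus Gaussian noise
  (the asymptotic sampling distribution of GWAS z-statistics);
* block-structured LD reference panels with population-specific MAF;
* individual-level cohorts in which cluster partitioned polygenic scores
  (pPS) shift T2D risk, log-BMI, and laboratory traits with stated effect
  sizes, and ancestry groups differ in mean pPS through allele frequencies;
* cell-type interval annotations enriched for the causal variants of chosen
  clusters.

Every generator is a pure function of its parameters and a seed, and the
:class:`PlantedTruth` object records the ground truth that downstream
parameter-recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .gwas_io import (
    AnnotationSet,
    AssociationStat,
    CohortTable,
    GwasStudy,
    LdPanel,
    VariantKey,
)

import pandas as pd

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

DEFAULT_ANCESTRIES = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass
class CohortEffects:
    """Per-cluster generative effects used by :func:`generate_cohort`.

    ``t2d_logor``: log-odds of T2D per SD of cluster pPS. ``log_bmi``:
    effect on log-BMI per SD of pPS. ``labs``: per-lab effect on the
    (standard-normal) lab value per SD of pPS.
    """

    t2d_logor: np.ndarray
    log_bmi: np.ndarray
    labs: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    """Ground truth behind every synthetic dataset."""

    K_true: int
    W_true: np.ndarray  # variants x K, >= 0
    H_true: np.ndarray  # K x traits, >= 0
    variants: list[VariantKey]
    trait_labels: list[str]
    trait_signs: np.ndarray  # +1/-1 per trait, fixed
    noise_sd: float
    cluster_of_variant: np.ndarray  # planted hard assignment, -1 = background
    causal_sets: dict[int, set[VariantKey]]
    cohort_effects: CohortEffects
    ancestry_pps_shift: dict[str, np.ndarray]
    seed: int

    def __post_init__(self):
        if np.any(self.W_true < 0) or np.any(self.H_true < 0):
            raise ValueError("planted factors must be non-negative")

    @property
    def signal(self) -> np.ndarray:
        """The planted signed z-score matrix without noise."""
        return self.trait_signs[None, :] * (self.W_true @ self.H_true)

    def members(self, k: int) -> set[VariantKey]:
        idx = np.where(self.cluster_of_variant == k)[0]
        return {self.variants[i] for i in idx}


def make_planted_truth(
    K_true: int = 4,
    n_variants: int = 200,
    n_traits: int = 40,
    seed: int = 0,
    noise_frac: float = 0.1,
    variant_weight_range: tuple[float, float] = (1.0, 1.3),
    trait_weight_range: tuple[float, float] = (4.5, 6.5),
    t2d_logor: np.ndarray | None = None,
    log_bmi_effect: np.ndarray | None = None,
    lab_effects: dict[str, np.ndarray] | None = None,
    ancestry_pps_shift: dict[str, np.ndarray] | None = None,
    n_causal_per_cluster: int = 8,
) -> PlantedTruth:
    """Construct a planted truth with disjoint variant/trait memberships.

    Variants and traits are partitioned evenly across the ``K_true``
    clusters; member loadings are drawn uniformly from the given ranges so
    that typical planted signal cells have |z| around 5-8 (genome-wide
    significant scale), and ``noise_sd`` defaults to ``noise_frac`` times
    the mean planted signal magnitude.
    """
    rng = np.random.default_rng(seed)
    variants = []
    for i in range(n_variants):
        a1, a2 = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        chrom = str(1 + (i % 4))
        pos = 1_000_000 + 1_000_000 * (i // 4)
        variants.append(VariantKey(chrom, pos, a1, a2, rsid=f"rs{i + 1}"))
    trait_labels = [f"trait{j + 1:02d}" for j in range(n_traits)]
    cluster_of_variant = np.repeat(np.arange(K_true), int(np.ceil(n_variants / K_true)))[:n_variants]
    cluster_of_trait = np.repeat(np.arange(K_true), int(np.ceil(n_traits / K_true)))[:n_traits]
    W = np.zeros((n_variants, K_true))
    H = np.zeros((K_true, n_traits))
    W[np.arange(n_variants), cluster_of_variant] = rng.uniform(*variant_weight_range, n_variants)
    H[cluster_of_trait, np.arange(n_traits)] = rng.uniform(*trait_weight_range, n_traits)
    trait_signs = rng.choice([-1.0, 1.0], size=n_traits)
    signal = W @ H
    noise_sd = noise_frac * float(np.mean(signal[signal > 0]))
    causal_sets = {}
    for k in range(K_true):
        members = np.where(cluster_of_variant == k)[0]
        chosen = rng.choice(members, size=min(n_causal_per_cluster, members.size), replace=False)
        causal_sets[k] = {variants[i] for i in chosen}
    effects = CohortEffects(
        t2d_logor=np.asarray(t2d_logor if t2d_logor is not None else np.full(K_true, 0.15)),
        log_bmi=np.asarray(log_bmi_effect if log_bmi_effect is not None else np.zeros(K_true)),
        labs=lab_effects or {},
    )
    shifts = ancestry_pps_shift or {}
    shifts = {a: np.asarray(v, dtype=float) for a, v in shifts.items()}
    return PlantedTruth(
        K_true=K_true,
        W_true=W,
        H_true=H,
        variants=variants,
        trait_labels=trait_labels,
        trait_signs=trait_signs,
        noise_sd=noise_sd,
        cluster_of_variant=cluster_of_variant,
        causal_sets=causal_sets,
        cohort_effects=effects,
        ancestry_pps_shift=shifts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudies:
    """The GWAS inputs the matrix pipeline expects."""

    t2d_anchor: GwasStudy
    t2d_studies: list[GwasStudy]
    trait_studies: list[GwasStudy]


def _study_from_z(z, variants, label, n, rng, ancestry="MULTI", sex="combined"):
    beta = z / np.sqrt(n)
    se = np.full_like(beta, 1.0 / np.sqrt(n))
    p = 2.0 * sps.norm.sf(np.abs(z))
    eaf = rng.uniform(0.1, 0.9, size=len(variants))
    stats = [
        AssociationStat(
            key=v, effect_allele=v.allele1, beta=float(beta[i]), se=float(se[i]),
            p=float(min(p[i], 1.0)), n=float(n), eaf=float(eaf[i]),
        )
        for i, v in enumerate(variants)
    ]
    return GwasStudy(trait_label=label, ancestry_tag=ancestry, sex_tag=sex, stats=stats)


def generate_summary_stats(
    truth: PlantedTruth,
    ancestries: tuple[str, ...] = DEFAULT_ANCESTRIES,
    n_per_study: float = 100_000,
    seed: int | None = None,
) -> SyntheticStudies:
    """Generate T2D and trait GWAS realizing the planted factorization.

    Trait studies carry ``z = sign_t * (W_true @ H_true) + noise``; effect
    alleles are the designated risk alleles (``allele1``) so the anchor's
    risk-allele orientation is positive by construction. The anchor and the
    per-ancestry T2D studies place planted variants well past genome-wide
    significance (|z| in 6-12).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_variants = len(truth.variants)
    Z = truth.signal + rng.normal(0.0, truth.noise_sd, size=truth.signal.shape)
    trait_studies = [
        _study_from_z(Z[:, j], truth.variants, label, n_per_study, rng)
        for j, label in enumerate(truth.trait_labels)
    ]
    z_anchor = rng.uniform(6.0, 12.0, size=n_variants)
    anchor = _study_from_z(z_anchor, truth.variants, "T2D", 10 * n_per_study, rng)
    t2d_studies = []
    for anc in ancestries:
        z = z_anchor + rng.normal(0.0, 0.5, size=n_variants)
        t2d_studies.append(_study_from_z(z, truth.variants, f"T2D_{anc}", n_per_study, rng, ancestry=anc))
    return SyntheticStudies(t2d_anchor=anchor, t2d_studies=t2d_studies, trait_studies=trait_studies)


# ---------------------------------------------------------------------------
# LD panels
# ---------------------------------------------------------------------------

def generate_ld_panel(
    populations: list[str],
    blocks: list[list[VariantKey]],
    rho: float,
    maf_range: tuple[float, float] | dict[str, tuple[float, float]] = (0.05, 0.5),
    seed: int = 0,
    special_pair: tuple[VariantKey, VariantKey] | None = None,
    special_pair_population: str | None = None,
    special_pair_rho: float = 0.06,
) -> list[LdPanel]:
    """Block-diagonal LD panels, one per population.

    Within-block pairs get r2 = ``rho``; across blocks r2 = 0. MAF is drawn
    uniformly per population from ``maf_range``. ``special_pair`` can be
    given an elevated r2 in exactly one population to exercise the
    all-panels independence rule.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    panels = []
    for pop in populations:
        panel = LdPanel(pop)
        bounds = maf_range[pop] if isinstance(maf_range, dict) else maf_range
        for block in blocks:
            for v in block:
                panel.set_maf(v, float(rng.uniform(*bounds)))
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    if rho > 0:
                        panel.set_r2(block[i], block[j], rho)
        if special_pair is not None and pop == special_pair_population:
            panel.set_r2(special_pair[0], special_pair[1], special_pair_rho)
        panels.append(panel)
    return panels


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    truth: PlantedTruth,
    n: int,
    ancestry_mix: dict[str, float] | None = None,
    seed: int = 0,
    baseline_logit: float = -2.0,
    bmi_logit_coef: float = 4.0,
    ancestry_logit_offsets: dict[str, float] | None = None,
    mean_log_bmi: float = np.log(27.0),
    sd_log_bmi: float = 0.15,
    n_pcs: int = 10,
    lipid_med_rate: float = 0.2,
    outcome_effects: dict[str, np.ndarray] | None = None,
) -> CohortTable:
    """Simulate an individual-level cohort realizing the planted effects.

    Dosages are Binomial(2, f) with ancestry-specific frequencies chosen so
    that the mean cluster pPS of each ancestry is shifted relative to the
    baseline by ``truth.ancestry_pps_shift`` (in SD units of the pPS). T2D
    status follows ``logit = baseline + bmi_logit_coef*(logBMI - mean) +
    sum_k delta_k * pPS_k(std) + ancestry offset``; log-BMI and labs get the
    planted linear effects; PCs are linearly separable by ancestry.
    """
    if ancestry_mix is None:
        ancestry_mix = {"EUR": 1.0}
    props = np.array(list(ancestry_mix.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("ancestry_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    groups = list(ancestry_mix)
    K = truth.K_true
    variants = truth.variants
    V = len(variants)
    if n == 0:
        empty = pd.DataFrame(index=pd.Index([], name="iid"))
        return CohortTable(empty, pd.DataFrame(index=empty.index), {}, {})

    # base allele frequencies; seeded from truth so panels/cohorts agree
    f0 = np.random.default_rng(truth.seed + 1).uniform(0.3, 0.7, size=V)
    w = truth.W_true  # V x K, risk-allele weights
    var_k = (w**2 * (2.0 * f0 * (1.0 - f0))[:, None]).sum(axis=0)
    sd_k = np.sqrt(np.maximum(var_k, 1e-12))
    freq = {}
    for g in groups:
        shift = truth.ancestry_pps_shift.get(g, np.zeros(K))
        f = f0.copy()
        for k in range(K):
            members = truth.cluster_of_variant == k
            wk_sum = w[members, k].sum()
            if wk_sum > 0 and shift[k] != 0:
                f[members] = f[members] + shift[k] * sd_k[k] / (2.0 * wk_sum)
        freq[g] = np.clip(f, 0.02, 0.98)

    labels = rng.choice(groups, size=n, p=props)
    dosage = np.empty((n, V))
    for g in groups:
        mask = labels == g
        dosage[mask] = rng.binomial(2, freq[g], size=(mask.sum(), V))

    raw_pps = dosage @ w
    pps_std = (raw_pps - raw_pps.mean(axis=0)) / np.where(raw_pps.std(axis=0) > 0, raw_pps.std(axis=0), 1.0)

    eff = truth.cohort_effects
    log_bmi = mean_log_bmi + pps_std @ eff.log_bmi + rng.normal(0.0, sd_log_bmi, n)
    bmi = np.exp(log_bmi)
    offsets = np.array([(ancestry_logit_offsets or {}).get(g, 0.0) for g in labels])
    logit = baseline_logit + bmi_logit_coef * (log_bmi - mean_log_bmi) + pps_std @ eff.t2d_logor + offsets
    t2d = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    age = rng.uniform(20, 80, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    hba1c = np.round(rng.normal(5.4, 0.3, n) + 1.6 * t2d, 2)
    lipid_med = rng.random(n) < lipid_med_rate

    pcs = np.zeros((n, n_pcs))
    group_means = {g: np.zeros(n_pcs) for g in groups}
    for gi, g in enumerate(groups):
        m = np.zeros(n_pcs)
        m[gi % n_pcs] = 5.0
        m[(gi + 1) % n_pcs] = -3.0 * (gi + 1)
        group_means[g] = m
    for g in groups:
        mask = labels == g
        pcs[mask] = group_means[g] + rng.normal(0.0, 0.3, size=(mask.sum(), n_pcs))

    data = {
        "age": np.round(age, 1),
        "sex": sex,
        "ancestry_label": labels,
        "bmi": np.round(bmi, 2),
        "t2d_status": t2d.astype(int),
        "hba1c_max": hba1c,
        "lipid_med": lipid_med.astype(int),
    }
    for j in range(n_pcs):
        data[f"PC{j + 1}"] = np.round(pcs[:, j], 4)
    for lab, lam in eff.labs.items():
        # labs are concentrations: unit-SD values around a positive offset
        data[f"lab_{lab}"] = np.round(10.0 + pps_std @ np.asarray(lam) + rng.normal(0.0, 1.0, n), 4)
    for outcome, gamma in (outcome_effects or {}).items():
        lo = -2.0 + pps_std @ np.asarray(gamma)
        data[f"outcome_{outcome}"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-lo))).astype(int)

    index = pd.Index([f"I{i + 1:06d}" for i in range(n)], name="iid")
    samples = pd.DataFrame(data, index=index)
    dosages = pd.DataFrame(dosage, index=index, columns=[v.vid for v in variants])
    counted = {v.vid: v.allele1 for v in variants}  # allele1 is the risk allele
    vmap = {v.vid: v for v in variants}
    return CohortTable(samples, dosages, counted, vmap)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    truth: PlantedTruth,
    cell_types: list[str],
    enriched_pairs: list[tuple[int, str]],
    coverage: float = 0.05,
    seed: int = 0,
    halfwidth: int = 500,
) -> list[AnnotationSet]:
    """Cell-type interval sets; enriched pairs cover a cluster's causal variants.

    Every annotation covers a random ``coverage`` fraction of all variant
    positions as background; for each ``(cluster, cell_type)`` in
    ``enriched_pairs`` the annotation additionally covers every causal
    variant of that cluster with a +/- ``halfwidth`` bp interval.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    enriched_by_ct: dict[str, list[int]] = {}
    for k, ct in enriched_pairs:
        enriched_by_ct.setdefault(ct, []).append(k)
    out = []
    for ct in cell_types:
        ann = AnnotationSet(ct)
        for v in truth.variants:
            if rng.random() < coverage:
                ann.add(v.chrom, max(0, v.pos - 1 - halfwidth), v.pos + halfwidth)
        for k in enriched_by_ct.get(ct, []):
            for v in sorted(truth.causal_sets[k], key=lambda x: (x.chrom, x.pos)):
                ann.add(v.chrom, max(0, v.pos - 1 - halfwidth), v.pos + halfwidth)
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# fine-mapping inputs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLocus:
    """One locus for credible-set construction: index, region stats, panel."""

    cluster: int
    index: VariantKey
    region_stats: list[AssociationStat]
    panel: LdPanel


def generate_finemap_inputs(
    truth: PlantedTruth,
    n_region: int = 8,
    seed: int = 0,
    n_gwas: float = 100_000,
    index_z: float = 8.0,
) -> list[SyntheticLocus]:
    """One locus per causal variant: the index plus nearby correlated variants.

    Non-index variants sit within +/-100 kb, have r2 to the index drawn from
    U(0.15, 0.9), and z-scores ``index_z * sqrt(r2)`` plus noise, so the
    index carries most of the posterior mass.
    """
    rng = np.random.default_rng(seed)
    loci = []
    for k in sorted(truth.causal_sets):
        for index in sorted(truth.causal_sets[k], key=lambda v: (v.chrom, v.pos)):
            panel = LdPanel(f"locus_{index.vid}")
            region = []
            z_idx = index_z + rng.normal(0, 0.5)
            se = 1.0 / np.sqrt(n_gwas)
            region.append(
                AssociationStat(
                    key=index, effect_allele=index.allele1, beta=float(z_idx * se), se=se,
                    p=float(min(2 * sps.norm.sf(abs(z_idx)), 1.0)), n=n_gwas,
                )
            )
            panel.set_maf(index, 0.3)
            for j in range(n_region - 1):
                offset = int(rng.integers(1_000, 100_000)) * (1 if j % 2 == 0 else -1)
                a1, a2 = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
                v = VariantKey(index.chrom, max(1, index.pos + offset), a1, a2)
                r2 = float(rng.uniform(0.15, 0.9))
                z = float(z_idx * np.sqrt(r2) + rng.normal(0, 0.5))
                region.append(
                    AssociationStat(
                        key=v, effect_allele=v.allele1, beta=z * se, se=se,
                        p=float(min(2 * sps.norm.sf(abs(z)), 1.0)), n=n_gwas,
                    )
                )
                panel.set_r2(index, v, r2)
                panel.set_maf(v, 0.3)
            loci.append(SyntheticLocus(cluster=k, index=index, region_stats=region, panel=panel))
    return loci
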