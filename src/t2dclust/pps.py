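"""Partitioned polygenic scores (pPS).

A cluster's pPS for an individual is the weighted sum of risk-allele
dosages over the cluster's above-threshold variants, with the bNMF weight
as the variant weight. When individual-level genotypes are unavailable, a
cluster-trait association is estimated from GWAS summary statistics alone
by inverse-variance-weighted (IVW) fixed-effects meta-analysis of the
cluster variants' trait effects (the "GWAS-pPS").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bnmf import ClusterSolution
from .gwas_io import CohortTable, GwasStudy, VariantKey, logger


@dataclass
class ClusterVariant:
    key: VariantKey
    weight: float
    risk_allele: str


@dataclass
class PartitionedScoreMatrix:
    """Per-individual, per-cluster scores, raw and standardized."""

    raw: pd.DataFrame            # individuals x clusters
    standardized: pd.DataFrame   # z-scored per cluster over the cohort
    variant_lists: dict[str, list[ClusterVariant]]
    missing_policy_log: list[dict] = field(default_factory=list)

    @property
    def clusters(self) -> list[str]:
        return list(self.raw.columns)


@dataclass
class MetaAnalysisResult:
    """Pooled effect from fixed- or random-effects meta-analysis."""

    beta: float
    se: float
    p: float
    n: int                       # variants (IVW) or studies (random-effects)
    tau2: float = 0.0
    method: str = "IVW-fixed"
    absent: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError("pooled se must be positive")


def cluster_variant_lists(
    sol: ClusterSolution,
    risk_alleles: dict[str, str],
    variant_keys: dict[str, VariantKey],
) -> dict[str, list[ClusterVariant]]:
    """Above-threshold variants per cluster, with bNMF weights and risk alleles.

    ``risk_alleles`` / ``variant_keys`` map canonical variant ids (the row
    labels of ``sol.W``) to the T2D risk allele and the full key.
    """
    out: dict[str, list[ClusterVariant]] = {}
    for c in sol.cluster_labels:
        out[c] = [
            ClusterVariant(key=variant_keys[vid], weight=w, risk_allele=risk_alleles[vid])
            for vid, w in sol.variant_members(c).items()
        ]
    return out


def individual_pps(cohort: CohortTable, sol: ClusterSolution,
                   risk_alleles: dict[str, str] | None = None) -> PartitionedScoreMatrix:
    """Individual-level pPS: weighted risk-allele dosage sums per cluster.

    Dosages counting the non-risk allele are flipped (2 - d); missing
    dosages are imputed as twice the cohort risk-allele frequency, with
    each imputation logged. Standardized columns are z-scored over the full
    cohort (mean 0, SD 1), giving the per-SD effect convention downstream.
    """
    if risk_alleles is None:
        risk_alleles = cohort.counted_alleles
    variant_keys = cohort.variants
    lists = cluster_variant_lists(sol, risk_alleles, variant_keys)
    for c, lst in lists.items():
        if not lst:
            raise ValueError(f"cluster {c} has no variants above the weight threshold")

    aligned: dict[str, np.ndarray] = {}
    log: list[dict] = []
    for vid in {cv.key.vid for lst in lists.values() for cv in lst}:
        if vid not in cohort.dosages.columns:
            raise KeyError(f"variant {vid} missing from cohort dosages")
        d = cohort.dosages[vid].to_numpy(dtype=float)
        if cohort.counted_alleles[vid] != risk_alleles[vid]:
            d = 2.0 - d
        freq = np.nanmean(d) / 2.0 if np.isfinite(d).any() else 0.0
        miss = ~np.isfinite(d)
        if miss.any():
            d = np.where(miss, 2.0 * freq, d)
            for iid in cohort.dosages.index[miss]:
                log.append({"iid": iid, "variant": vid, "imputed_dosage": 2.0 * freq})
        aligned[vid] = d

    raw = pd.DataFrame(index=cohort.samples.index)
    for c, lst in lists.items():
        raw[c] = sum(cv.weight * aligned[cv.key.vid] for cv in lst)
    sd = raw.std(axis=0, ddof=0).replace(0.0, 1.0)
    standardized = (raw - raw.mean(axis=0)) / sd
    return PartitionedScoreMatrix(raw=raw, standardized=standardized,
                                  variant_lists=lists, missing_policy_log=log)


def ivw_fixed(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Inverse-variance-weighted fixed-effects pool of per-unit effects."""
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return beta, se


def gwas_pps_meta(
    cluster_variants: list[ClusterVariant],
    trait_study: GwasStudy,
    use_cluster_weights: bool = False,
) -> MetaAnalysisResult:
    """Cluster-trait association from summary statistics by fixed-effects IVW.

    Per-variant trait effects are aligned to the T2D risk allele before
    pooling. By default the cluster enters only through variant selection;
    with ``use_cluster_weights`` each variant's effect (and se) is scaled
    by its bNMF cluster weight before pooling (sensitivity mode).
    """
    betas, ses, absent = [], [], []
    for cv in cluster_variants:
        s = trait_study.get(cv.key)
        if s is None:
            absent.append(cv.key.vid)
            continue
        s = s.aligned_to(cv.risk_allele)
        scale = cv.weight if use_cluster_weights else 1.0
        betas.append(scale * s.beta)
        ses.append(scale * s.se)
    if not betas:
        raise ValueError(f"no cluster variant present in study {trait_study.label}")
    if absent:
        logger.info("%d cluster variant(s) absent from %s", len(absent), trait_study.label)
    beta, se = ivw_fixed(np.array(betas), np.array(ses))
    p = 2.0 * sps.norm.sf(abs(beta / se))
    return MetaAnalysisResult(beta=beta, se=se, p=float(p), n=len(betas), absent=absent)


def write_scores(scores: PartitionedScoreMatrix, prefix) -> None:
    scores.raw.rename_axis("iid").to_csv(f"{prefix}.raw.tsv", sep="\t")
    scores.standardized.rename_axis("iid").to_csv(f"{prefix}.std.tsv", sep="\t")
    rows = [
        {"cluster": c, "variant": cv.key.vid, "weight": cv.weight, "risk_allele": cv.risk_allele}
        for c, lst in scores.variant_lists.items()
        for cv in lst
    ]
    pd.DataFrame(rows).to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
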