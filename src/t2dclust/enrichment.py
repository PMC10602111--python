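"""Credible sets and cell-type regulatory enrichment.

For each association locus, a 99% credible set is built from Wakefield
approximate Bayes factors (aBFs) over the variants within a 500 kb window
that have r2 >= 0.1 with the index variant; each variant's posterior
probability of association (PPA) is its aBF normalized by the locus sum.
Per cluster and cell-type annotation, the enrichment statistic is the
cumulative posterior probability (cPPA) of credible-set variants falling
inside the annotation's intervals. Significance comes from a permutation
null that shuffles locus-to-cluster assignments jointly with
annotation-to-cell-type labels, with Benjamini-Hochberg FDR control across
all cluster-by-cell-type tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .gwas_io import AnnotationSet, AssociationStat, LdPanel, VariantKey


def wakefield_abf(stat: AssociationStat, prior_sd: float = 0.2) -> float:
    """Wakefield's approximate Bayes factor for one association.

    With V = se^2, W = prior_sd^2, z = beta/se:
    aBF = sqrt(V / (V + W)) * exp(z^2 W / (2 (V + W))); always positive,
    equal to sqrt(V/(V+W)) < 1 at z = 0, and tending to 1 as W -> 0.
    """
    V = stat.se**2
    W = prior_sd**2
    z = stat.z
    return math.sqrt(V / (V + W)) * math.exp(z * z * W / (2.0 * (V + W)))


@dataclass
class CredibleSet:
    """A 99% credible set for one locus."""

    index_variant: VariantKey
    members: list[tuple[VariantKey, float, float]]  # (variant, aBF, PPA), retained only
    mass: float                                     # sum of retained PPAs
    window: int = 500_000
    r2_floor: float = 0.1


def build_credible_set(
    index: VariantKey,
    region_stats: list[AssociationStat],
    panel: LdPanel,
    window: int = 500_000,
    r2_floor: float = 0.1,
    mass_target: float = 0.99,
    prior_sd: float = 0.2,
    normalize_after_truncation: bool = False,
) -> CredibleSet:
    """Build the credible set around an index variant.

    Candidates are the region variants within ``window``/2 of the index
    (a total window of ``window`` bp, index-centered) with r2 >= ``r2_floor``
    to the index. PPAs are aBFs normalized over the full candidate set, and
    members are retained in PPA-descending order until the cumulative PPA
    reaches ``mass_target``. With ``normalize_after_truncation`` the
    retained PPAs are renormalized to sum to 1 (alternative reading).
    """
    if not any(s.key == index for s in region_stats):
        raise ValueError(f"index variant {index.vid} not among region stats")
    half = window // 2
    candidates = [
        s for s in region_stats
        if s.key.chrom == index.chrom
        and abs(s.key.pos - index.pos) <= half
        and panel.r2(index, s.key) >= r2_floor
    ]
    if not candidates:
        raise ValueError(f"no candidate variants for index {index.vid}")
    abfs = np.array([wakefield_abf(s, prior_sd) for s in candidates])
    ppa = abfs / abfs.sum()
    order = np.argsort(-ppa, kind="stable")
    retained, cum = [], 0.0
    for i in order:
        retained.append((candidates[i].key, float(abfs[i]), float(ppa[i])))
        cum += float(ppa[i])
        if cum >= mass_target:
            break
    if normalize_after_truncation:
        total = sum(p for _, _, p in retained)
        retained = [(k, a, p / total) for k, a, p in retained]
        cum = 1.0
    return CredibleSet(index_variant=index, members=retained, mass=cum,
                       window=window, r2_floor=r2_floor)


def cluster_cppa(sets: list[CredibleSet], ann: AnnotationSet) -> float:
    """Cumulative posterior probability of a cluster's credible-set variants
    overlapping one annotation."""
    if not sets:
        raise ValueError("cluster has no credible sets")
    total = 0.0
    for cs in sets:
        for key, _, ppa in cs.members:
            if ann.contains(key.chrom, key.pos):
                total += ppa
    return total


@dataclass
class EnrichmentResult:
    cluster: str
    cell_type: str
    cppa_obs: float
    perm_p: float
    q: float = float("nan")
    significant_q10: bool = False
    significant_q001: bool = False


def permutation_enrichment(
    sets_by_cluster: dict[str, list[CredibleSet]],
    annotations: list[AnnotationSet],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation test of cPPA for every cluster-by-cell-type pair.

    Locus geometry and interval geometry are held fixed; each permutation
    shuffles the locus-to-cluster assignment and the annotation-to-cell-type
    labels jointly and recomputes every cPPA. One-tailed
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)`` (never exactly zero), then
    Benjamini-Hochberg q-values across all pairs with significance flags at
    q < 0.1 and q < 0.001.
    """
    clusters = sorted(sets_by_cluster)
    if len(clusters) < 2 or len(annotations) < 2:
        raise ValueError("need >= 2 clusters and >= 2 annotations for a permutation null")
    loci = [(c, cs) for c in clusters for cs in sets_by_cluster[c]]
    n_loci = len(loci)
    n_ann = len(annotations)
    # per-locus overlap mass against each annotation: loci x annotations
    O = np.zeros((n_loci, n_ann))
    for i, (_, cs) in enumerate(loci):
        for j, ann in enumerate(annotations):
            O[i, j] = sum(ppa for key, _, ppa in cs.members if ann.contains(key.chrom, key.pos))
    locus_cluster = np.array([clusters.index(c) for c, _ in loci])
    n_clusters = len(clusters)
    member_matrix = np.zeros((n_clusters, n_loci))
    member_matrix[locus_cluster, np.arange(n_loci)] = 1.0
    observed = member_matrix @ O  # clusters x annotations

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm_loci = rng.permutation(n_loci)
        perm_ann = rng.permutation(n_ann)
        # locus i takes the cluster label of locus perm_loci[i]; columns
        # take shuffled cell-type labels
        permuted = (member_matrix[:, perm_loci] @ O)[:, perm_ann]
        exceed += permuted >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    flat_p = pvals.ravel()
    _, qvals, _, _ = multipletests(flat_p, method="fdr_bh")
    qvals = qvals.reshape(pvals.shape)
    results = []
    for ci, c in enumerate(clusters):
        for aj, ann in enumerate(annotations):
            q = float(qvals[ci, aj])
            results.append(
                EnrichmentResult(
                    cluster=c, cell_type=ann.cell_type,
                    cppa_obs=float(observed[ci, aj]), perm_p=float(pvals[ci, aj]),
                    q=q, significant_q10=q < 0.1, significant_q001=q < 0.001,
                )
            )
    return results
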