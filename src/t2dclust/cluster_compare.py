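"""Quantitative comparison of cluster solutions.

Trait-weight Pearson correlations between two factorizations (on the
shared trait vocabulary), greedy best-match assignment of clusters, LD
proxy mapping of external variant lists onto the internal variant set, and
Wilcoxon rank-sum tests on transferred variant weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bnmf import ClusterSolution
from .gwas_io import LdPanel, VariantKey


@dataclass
class ComparisonResult:
    r_matrix: pd.DataFrame                       # clusters A x clusters B
    best_match: dict[str, str]                   # A -> B
    shared_traits: list[str]


def weight_correlation(
    solA: ClusterSolution,
    solB: ClusterSolution,
    optimal: bool = False,
) -> ComparisonResult:
    """Pearson R between trait cluster weights over the shared vocabulary.

    Matching is greedy by default (highest R first, without replacement),
    mirroring how correlation heatmaps between solutions are read; with
    ``optimal`` an optimal linear-sum assignment is used instead.
    """
    shared = [t for t in solA.H.columns if t in set(solB.H.columns)]
    if not shared:
        raise ValueError("no shared trait columns between solutions")
    A = solA.H[shared].to_numpy(dtype=float)
    B = solB.H[shared].to_numpy(dtype=float)
    R = np.zeros((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            if np.std(A[i]) == 0 or np.std(B[j]) == 0:
                R[i, j] = 0.0
            else:
                R[i, j] = float(np.corrcoef(A[i], B[j])[0, 1])
    r_matrix = pd.DataFrame(R, index=solA.H.index, columns=solB.H.index)
    best: dict[str, str] = {}
    if optimal:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-R)
        for i, j in zip(rows, cols):
            best[str(r_matrix.index[i])] = str(r_matrix.columns[j])
    else:
        taken_a: set[int] = set()
        taken_b: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(-R, axis=None), R.shape))[0]
        for i, j in order:
            if i in taken_a or j in taken_b:
                continue
            best[str(r_matrix.index[i])] = str(r_matrix.columns[j])
            taken_a.add(int(i))
            taken_b.add(int(j))
            if len(taken_a) == min(R.shape):
                break
    return ComparisonResult(r_matrix=r_matrix, best_match=best, shared_traits=shared)


def proxy_map(
    external_variants: list[VariantKey],
    internal_variants: list[VariantKey],
    panel: LdPanel,
    r2_floor: float = 0.5,
) -> dict[VariantKey, tuple[VariantKey, float] | None]:
    """Map each external variant to its best internal high-LD proxy.

    The internal variant with maximal r2 wins if that maximum exceeds
    ``r2_floor`` (an identical variant maps to itself at r2 = 1); ties are
    broken by smaller genomic distance, then lexicographic id. Unmatched
    variants map to None. Deterministic and idempotent.
    """
    out: dict[VariantKey, tuple[VariantKey, float] | None] = {}
    for ext in external_variants:
        best: tuple[VariantKey, float] | None = None
        for internal in internal_variants:
            r2 = panel.r2(ext, internal)
            if r2 <= r2_floor:
                continue
            if best is None:
                best = (internal, r2)
                continue
            cur = best[0]
            if (r2, -abs(internal.pos - ext.pos), ) > (best[1], -abs(cur.pos - ext.pos)):
                best = (internal, r2)
            elif r2 == best[1] and abs(internal.pos - ext.pos) == abs(cur.pos - ext.pos) \
                    and internal.vid < cur.vid:
                best = (internal, r2)
        out[ext] = best
    return out


def ranksum_compare(
    transferred_weights: dict[str, np.ndarray],
    cluster_pairs: list[tuple[str, str]],
    exact_max_n: int = 20,
) -> dict[tuple[str, str], float]:
    """Two-sided Wilcoxon rank-sum p-value per cluster pair.

    Exact enumeration is used for small tie-free samples, the normal
    approximation with tie correction otherwise.
    """
    out = {}
    for a, b in cluster_pairs:
        x = np.asarray(transferred_weights[a], dtype=float)
        y = np.asarray(transferred_weights[b], dtype=float)
        if x.size == 0 or y.size == 0:
            raise ValueError(f"empty weight sample in pair ({a}, {b})")
        has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "exact" if (max(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out[(a, b)] = float(min(res.pvalue, 1.0))
    return out
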