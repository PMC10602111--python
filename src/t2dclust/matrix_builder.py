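"""Preprocessing pipeline from raw GWAS summary statistics to the
risk-allele-aligned, standardized variant-by-trait z-score matrix.

Stages, in order:

1. ``select_t2d_variants`` — union of genome-wide-significant T2D variants,
   minus indels, the MHC region, anchor-discordant or anchor-weak variants;
   each survivor is annotated with its risk allele from the anchor study.
2. ``ld_prune_multi`` — greedy LD pruning run independently against every
   population reference panel; a variant survives only if independent in
   all panels.
3. ``resolve_proxies`` — high-missingness, multi-allelic, or strand-ambiguous
   variants are replaced by a high-LD (r2 > 0.8) proxy or dropped.
4. ``select_traits`` — drop underpowered (median N < 5,000), non-significant
   (Bonferroni over the variant count), and redundant (|R| > 0.80) traits.
5. ``assemble_matrix`` — align z-scores to the T2D risk allele, fill missing
   cells from proxies (r2 > 0.5) or the trait median, standardize columns.

Each stage returns its result plus attrition bookkeeping so a run can be
audited rule by rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import AssociationStat, GwasStudy, LdPanel, VariantKey, logger


@dataclass
class PipelineConfig:
    """Numeric rules of the preprocessing pipeline (defaults per the method)."""

    p_threshold: float = 5e-8           # 5e-6 for AFR/AMR ancestry-specific runs
    prune_r2: float = 0.05
    prune_maf_min: float = 0.001
    proxy_r2: float = 0.8
    fill_proxy_r2: float = 0.5
    anchor_p_max: float = 0.05
    trait_min_median_n: float = 5000.0
    trait_corr_max: float = 0.80
    mhc_region: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)  # 1-based inclusive
    missingness_max: float = 0.20       # proxy-substitution trigger
    matrix_missing_max: float = 0.5     # hard failure after proxy fill

    def __post_init__(self):
        for name in ("prune_r2", "proxy_r2", "fill_proxy_r2", "trait_corr_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0,1)")


@dataclass
class RiskVariant:
    """A selected variant with its T2D risk allele (anchor orientation)."""

    key: VariantKey
    risk_allele: str
    anchor_p: float


@dataclass
class VariantTraitMatrix:
    """Risk-allele-aligned, standardized z-score matrix with provenance.

    ``z`` is variants x traits (rows indexed by canonical variant id,
    columns by sex-suffixed trait label); ``provenance`` has the same shape
    with cell tags ``observed``, ``proxy:<r2>:<vid>``, or ``median``;
    ``scaling_meta`` records the per-trait centering/scaling parameters.
    """

    variants: list[RiskVariant]
    traits: list[str]
    z: pd.DataFrame
    provenance: pd.DataFrame
    scaling_meta: pd.DataFrame

    def __post_init__(self):
        if self.z.shape != self.provenance.shape:
            raise ValueError("z and provenance shapes differ")
        if list(self.z.columns) != self.traits or len(self.z) != len(self.variants):
            raise ValueError("matrix dimensions inconsistent with variant/trait lists")


def _in_mhc(key: VariantKey, region: tuple[str, int, int]) -> bool:
    chrom, start, end = region
    c = key.chrom.removeprefix("chr")
    return c == str(chrom).removeprefix("chr") and start <= key.pos <= end


def select_t2d_variants(
    t2d_studies: list[GwasStudy],
    anchor: GwasStudy,
    cfg: PipelineConfig,
    report: dict | None = None,
) -> list[RiskVariant]:
    """Union of significant T2D variants, filtered and risk-allele-annotated.

    A variant enters if its p-value beats ``cfg.p_threshold`` in any input
    study. Indels, MHC-region variants, variants absent from the anchor or
    with anchor p > ``cfg.anchor_p_max``, and variants whose risk allele
    (positive-beta orientation) disagrees between any significant source
    study and the anchor are removed.
    """
    candidates: dict[VariantKey, list[AssociationStat]] = {}
    for study in t2d_studies:
        for s in study.stats:
            if s.p < cfg.p_threshold:
                candidates.setdefault(s.key, []).append(s)
    counts = {"candidates": len(candidates), "indel": 0, "mhc": 0,
              "absent_from_anchor": 0, "anchor_p": 0, "risk_allele_discordant": 0}
    out: list[RiskVariant] = []
    for key in sorted(candidates, key=lambda k: (k.chrom, k.pos, k.alleles)):
        if key.is_indel:
            counts["indel"] += 1
            continue
        if _in_mhc(key, cfg.mhc_region):
            counts["mhc"] += 1
            continue
        a = anchor.get(key)
        if a is None:
            counts["absent_from_anchor"] += 1
            logger.info("variant %s absent from anchor study; removed", key.vid)
            continue
        if a.p > cfg.anchor_p_max:
            counts["anchor_p"] += 1
            continue
        # risk allele = allele with beta > 0 orientation in the anchor
        anchor_risk = a.effect_allele if a.beta >= 0 else a.key.other_allele(a.effect_allele)
        discordant = False
        for s in candidates[key]:
            source_risk = s.effect_allele if s.beta >= 0 else s.key.other_allele(s.effect_allele)
            if source_risk != anchor_risk:
                discordant = True
                break
        if discordant:
            counts["risk_allele_discordant"] += 1
            continue
        out.append(RiskVariant(key=key, risk_allele=anchor_risk, anchor_p=a.p))
    counts["selected"] = len(out)
    if report is not None:
        report["select_t2d_variants"] = counts
    return out


def ld_prune_multi(
    variants: list[RiskVariant],
    panels: list[LdPanel],
    cfg: PipelineConfig,
    report: dict | None = None,
) -> list[RiskVariant]:
    """Greedy LD pruning per panel; keep variants independent in ALL panels.

    Within each panel, variants below the MAF floor are excluded, then the
    remainder are visited in a deterministic order (anchor p ascending,
    position as tie-break); a variant is pruned if its r2 with an
    already-kept variant reaches ``cfg.prune_r2`` — so within a correlated
    pair the smaller-anchor-p member survives. The final set is the
    intersection of the per-panel survivors.
    """
    if not panels:
        raise ValueError("at least one LD panel is required")
    order = sorted(variants, key=lambda rv: (rv.anchor_p, rv.key.chrom, rv.key.pos, rv.key.alleles))
    survivors_per_panel = []
    for panel in panels:
        eligible = []
        for rv in order:
            maf = panel.maf(rv.key)
            # absent MAF treated as passing (panel does not contradict retention)
            if maf is not None and maf < cfg.prune_maf_min:
                continue
            eligible.append(rv)
        kept: list[RiskVariant] = []
        for rv in eligible:
            if all(panel.r2(rv.key, other.key) < cfg.prune_r2 for other in kept):
                kept.append(rv)
        survivors_per_panel.append({rv.key for rv in kept})
    final_keys = set.intersection(*survivors_per_panel)
    out = [rv for rv in order if rv.key in final_keys]
    out.sort(key=lambda rv: (rv.key.chrom, rv.key.pos, rv.key.alleles))
    if report is not None:
        report["ld_prune_multi"] = {
            "input": len(variants),
            "survivors_per_panel": [len(s) for s in survivors_per_panel],
            "selected": len(out),
        }
    return out


def _missingness(rv: RiskVariant, trait_studies: list[GwasStudy]) -> float:
    if not trait_studies:
        return 0.0
    absent = sum(1 for st in trait_studies if rv.key not in st)
    return absent / len(trait_studies)


def resolve_proxies(
    variants: list[RiskVariant],
    trait_studies: list[GwasStudy],
    panels: list[LdPanel],
    cfg: PipelineConfig,
    proxy_candidates: list[RiskVariant] | None = None,
    report: dict | None = None,
) -> tuple[list[RiskVariant], dict[str, tuple[str, float]]]:
    """Replace problem variants with high-LD proxies, or drop them.

    A variant needs replacement when it is strand-ambiguous (A/T or C/G),
    multi-allelic in the trait studies, or missing from more than
    ``cfg.missingness_max`` of trait studies. The best proxy is the
    candidate with the highest maximum r2 across panels, required to exceed
    ``cfg.proxy_r2``; the proxy inherits the risk-allele orientation by LD
    sign convention (its anchor risk allele). Returns the updated list and
    an ``original vid -> (proxy vid, r2)`` substitution map.
    """
    proxy_candidates = proxy_candidates or []
    kept_keys = {rv.key for rv in variants}

    def multi_allelic(rv: RiskVariant) -> bool:
        seen: set[tuple[str, str]] = set()
        for st in trait_studies:
            s = st.get(rv.key)
            if s is not None:
                seen.add(s.key.alleles)
        for st in trait_studies:
            for s in st.stats:
                if (s.key.chrom, s.key.pos) == (rv.key.chrom, rv.key.pos) and s.key.alleles != rv.key.alleles:
                    return True
        return len(seen) > 1

    out: list[RiskVariant] = []
    substitutions: dict[str, tuple[str, float]] = {}
    counts = {"unchanged": 0, "replaced": 0, "dropped": 0}
    for rv in variants:
        needs = rv.key.is_strand_ambiguous or multi_allelic(rv) or _missingness(rv, trait_studies) > cfg.missingness_max
        if not needs:
            out.append(rv)
            counts["unchanged"] += 1
            continue
        best, best_r2 = None, cfg.proxy_r2
        for cand in proxy_candidates:
            if cand.key == rv.key or cand.key in kept_keys or cand.key.is_strand_ambiguous:
                continue
            r2 = max(panel.r2(rv.key, cand.key) for panel in panels)
            if r2 > best_r2 or (best is not None and r2 == best_r2 and cand.anchor_p < best.anchor_p):
                best, best_r2 = cand, r2
        if best is None:
            counts["dropped"] += 1
            logger.info("variant %s needs a proxy but none exceeds r2 %.2f; dropped", rv.key.vid, cfg.proxy_r2)
            continue
        substitutions[rv.key.vid] = (best.key.vid, best_r2)
        kept_keys.add(best.key)
        out.append(best)
        counts["replaced"] += 1
    if report is not None:
        report["resolve_proxies"] = counts
    return out, substitutions


def _aligned_z(study: GwasStudy, rv: RiskVariant) -> float | None:
    s = study.get(rv.key)
    if s is None:
        return None
    return s.aligned_to(rv.risk_allele).z


def select_traits(
    trait_studies: list[GwasStudy],
    variants: list[RiskVariant],
    cfg: PipelineConfig,
    report: dict | None = None,
) -> list[GwasStudy]:
    """Filter traits by power, significance, and mutual correlation.

    Traits with median N below the floor are dropped; traits whose minimum
    p across the final variants exceeds the Bonferroni level 0.05/M are
    dropped; then among pairs whose z-vectors (on pairwise-complete cells)
    correlate with |R| above the ceiling, the trait with the larger maximum
    absolute variant association is kept, iterating greedily.
    """
    M = len(variants)
    counts = {"input": len(trait_studies), "median_n": 0, "bonferroni": 0,
              "all_missing": 0, "correlated": 0}
    kept: list[GwasStudy] = []
    for st in trait_studies:
        if st.median_n < cfg.trait_min_median_n:
            counts["median_n"] += 1
            continue
        ps = [st.get(rv.key).p for rv in variants if rv.key in st]
        if not ps:
            counts["all_missing"] += 1
            logger.info("trait %s has no observed variants; dropped", st.label)
            continue
        if min(ps) > 0.05 / M:
            counts["bonferroni"] += 1
            continue
        kept.append(st)

    zvec = {
        st.label: np.array([np.nan if (z := _aligned_z(st, rv)) is None else z for rv in variants])
        for st in kept
    }
    max_abs = {st.label: float(np.nanmax(np.abs(zvec[st.label]))) for st in kept}

    def corr(a: str, b: str) -> float:
        x, y = zvec[a], zvec[b]
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
            return 0.0
        return float(np.corrcoef(x[mask], y[mask])[0, 1])

    while True:
        worst = None  # (|R|, loser label)
        labels = [st.label for st in kept]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                r = abs(corr(labels[i], labels[j]))
                if r > cfg.trait_corr_max:
                    loser = labels[j] if max_abs[labels[i]] >= max_abs[labels[j]] else labels[i]
                    if worst is None or r > worst[0]:
                        worst = (r, loser)
        if worst is None:
            break
        kept = [st for st in kept if st.label != worst[1]]
        counts["correlated"] += 1
    counts["selected"] = len(kept)
    if report is not None:
        report["select_traits"] = counts
    return kept


def assemble_matrix(
    variants: list[RiskVariant],
    kept_traits: list[GwasStudy],
    panels: list[LdPanel],
    cfg: PipelineConfig,
    report: dict | None = None,
) -> VariantTraitMatrix:
    """Assemble the standardized risk-allele-aligned z-score matrix.

    Missing cells are filled from the best proxy among the matrix variants
    with r2 > ``cfg.fill_proxy_r2`` (the proxy's aligned z for the same
    trait), else the trait's median observed z. Each column is then centered
    and scaled to unit variance over its observed cells' statistics.
    """
    vids = [rv.key.vid for rv in variants]
    labels = [st.label for st in kept_traits]
    z = pd.DataFrame(np.nan, index=vids, columns=labels)
    prov = pd.DataFrame("", index=vids, columns=labels)
    for st in kept_traits:
        for rv in variants:
            val = _aligned_z(st, rv)
            if val is not None:
                z.loc[rv.key.vid, st.label] = val
                prov.loc[rv.key.vid, st.label] = "observed"

    by_key = {rv.key: rv for rv in variants}
    for st in kept_traits:
        col = z[st.label]
        median = float(np.nanmedian(col.to_numpy())) if col.notna().any() else 0.0
        for rv in variants:
            if not np.isnan(z.loc[rv.key.vid, st.label]):
                continue
            best, best_r2 = None, cfg.fill_proxy_r2
            for other in variants:
                if other.key == rv.key or np.isnan(z.loc[other.key.vid, st.label]):
                    continue
                if prov.loc[other.key.vid, st.label] != "observed":
                    continue
                r2 = max(panel.r2(rv.key, other.key) for panel in panels)
                if r2 > best_r2:
                    best, best_r2 = other, r2
            if best is not None:
                z.loc[rv.key.vid, st.label] = z.loc[best.key.vid, st.label]
                prov.loc[rv.key.vid, st.label] = f"proxy:{best_r2:.3f}:{best.key.vid}"
            else:
                z.loc[rv.key.vid, st.label] = median
                prov.loc[rv.key.vid, st.label] = "median"

    missing_frac = (prov == "").to_numpy().mean(axis=1) if len(labels) else np.zeros(len(vids))
    if len(labels) and missing_frac.max() > cfg.matrix_missing_max:
        bad = [vids[i] for i in np.where(missing_frac > cfg.matrix_missing_max)[0]]
        raise ValueError(
            f"variants {bad} remain missing in > {cfg.matrix_missing_max:.0%} of traits; "
            "revisit proxy resolution"
        )

    scaling = []
    for label in labels:
        col = z[label].to_numpy(dtype=float)
        mu, sd = float(np.mean(col)), float(np.std(col))
        if sd == 0:
            sd = 1.0
        z[label] = (col - mu) / sd
        scaling.append({"trait": label, "center": mu, "scale": sd})
    scaling_meta = pd.DataFrame(scaling).set_index("trait") if scaling else pd.DataFrame(columns=["center", "scale"])
    if report is not None:
        report["assemble_matrix"] = {
            "cells": int(z.size),
            "observed": int((prov.to_numpy() == "observed").sum()),
            "proxy": int(np.char.startswith(prov.to_numpy().astype(str), "proxy").sum()),
            "median": int((prov.to_numpy() == "median").sum()),
        }
    return VariantTraitMatrix(variants=variants, traits=labels, z=z, provenance=prov, scaling_meta=scaling_meta)


def build_matrix(
    t2d_studies: list[GwasStudy],
    anchor: GwasStudy,
    trait_studies: list[GwasStudy],
    panels: list[LdPanel],
    cfg: PipelineConfig | None = None,
) -> tuple[VariantTraitMatrix, dict]:
    """Run the full preprocessing pipeline; returns the matrix and the
    per-rule attrition report."""
    cfg = cfg or PipelineConfig()
    report: dict = {}
    selected = select_t2d_variants(t2d_studies, anchor, cfg, report)
    pruned = ld_prune_multi(selected, panels, cfg, report)
    resolved, subs = resolve_proxies(pruned, trait_studies, panels, cfg,
                                     proxy_candidates=selected, report=report)
    report["proxy_substitutions"] = subs
    traits = select_traits(trait_studies, resolved, cfg, report)
    matrix = assemble_matrix(resolved, traits, panels, cfg, report)
    return matrix, report
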