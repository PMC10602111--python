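"""Variant/trait selection rules and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from t2dclust.gwas_io import AssociationStat, GwasStudy, LdPanel, VariantKey
from t2dclust.matrix_builder import (
    PipelineConfig,
    RiskVariant,
    assemble_matrix,
    build_matrix,
    ld_prune_multi,
    resolve_proxies,
    select_t2d_variants,
    select_traits,
)

from conftest import stat


def make_study(label, stats, **kw):
    return GwasStudy(label, stats=stats, **kw)


@pytest.fixture()
def cfg():
    return PipelineConfig()


class TestSelectVariants:
    def _anchor_stat(self, key, beta=0.1, p=1e-10):
        return stat(key, key.allele1, beta=beta, p=p)

    def test_threshold_indel_mhc_anchor_rules(self, cfg):
        keep = VariantKey("1", 100, "A", "G")
        weak = VariantKey("1", 200, "T", "C")          # p above threshold
        indel = VariantKey("1", 300, "AT", "A")
        mhc = VariantKey("6", 26_000_000, "A", "G")
        anchor_weak = VariantKey("2", 400, "A", "C")   # anchor p = 0.06
        absent = VariantKey("3", 500, "T", "G")        # not in anchor
        t2d = make_study("T2D_EUR", [
            stat(keep, "A", 0.1, p=4e-8),
            stat(weak, "T", 0.1, p=6e-8),
            stat(indel, "AT", 0.1, p=1e-9),
            stat(mhc, "A", 0.1, p=1e-9),
            stat(anchor_weak, "A", 0.1, p=1e-9),
            stat(absent, "T", 0.1, p=1e-9),
        ])
        anchor = make_study("T2D", [
            self._anchor_stat(keep),
            self._anchor_stat(weak),
            self._anchor_stat(indel),
            self._anchor_stat(mhc),
            self._anchor_stat(anchor_weak, p=0.06),
        ])
        out = select_t2d_variants([t2d], anchor, cfg)
        assert [rv.key for rv in out] == [keep]
        assert out[0].risk_allele == "A"

    def test_risk_allele_discordance_removed(self, cfg):
        v = VariantKey("1", 100, "A", "G")
        t2d = make_study("T2D_EAS", [stat(v, "A", beta=-0.1, p=1e-9)])  # risk allele G
        anchor = make_study("T2D", [stat(v, "A", beta=0.1, p=1e-9)])    # risk allele A
        assert select_t2d_variants([t2d], anchor, cfg) == []

    def test_relaxed_ancestry_threshold(self, cfg):
        v = VariantKey("1", 100, "A", "G")
        t2d = make_study("T2D_AFR", [stat(v, "A", 0.1, p=4e-6)], ancestry_tag="AFR")
        anchor = make_study("T2D", [stat(v, "A", 0.1, p=1e-4)])
        assert select_t2d_variants([t2d], anchor, cfg) == []
        afr_cfg = PipelineConfig(p_threshold=5e-6)
        assert [rv.key for rv in select_t2d_variants([t2d], anchor, afr_cfg)] == [v]

    def test_relaxing_threshold_is_monotone(self, cfg):
        rng = np.random.default_rng(0)
        keys = [VariantKey("1", 100 + i, "A", "G") for i in range(30)]
        ps = 10.0 ** rng.uniform(-12, -4, 30)
        t2d = make_study("T2D_EUR", [stat(k, "A", 0.1, p=float(p)) for k, p in zip(keys, ps)])
        anchor = make_study("T2D", [stat(k, "A", 0.1, p=1e-9) for k in keys])
        strict = {rv.key for rv in select_t2d_variants([t2d], anchor, cfg)}
        loose = {rv.key for rv in select_t2d_variants([t2d], anchor, PipelineConfig(p_threshold=5e-6))}
        assert strict <= loose


class TestLdPrune:
    def _rv(self, key, p):
        return RiskVariant(key=key, risk_allele=key.allele1, anchor_p=p)

    def test_pair_failing_in_one_panel_loses_weaker_member(self, cfg):
        a, b = VariantKey("1", 100, "A", "G"), VariantKey("1", 200, "T", "C")
        rvs = [self._rv(a, 1e-10), self._rv(b, 1e-8)]
        panels = [LdPanel(t) for t in ("AFR", "AMR", "EAS", "EUR", "SAS")]
        panels[2].set_r2(a, b, 0.06)  # fails independence in exactly one panel
        out = ld_prune_multi(rvs, panels, cfg)
        assert [rv.key for rv in out] == [a]

    def test_pair_below_threshold_everywhere_both_kept(self, cfg):
        a, b = VariantKey("1", 100, "A", "G"), VariantKey("1", 200, "T", "C")
        rvs = [self._rv(a, 1e-10), self._rv(b, 1e-8)]
        panels = [LdPanel(t) for t in ("AFR", "EUR")]
        for p in panels:
            p.set_r2(a, b, 0.04)
        assert len(ld_prune_multi(rvs, panels, cfg)) == 2

    def test_single_panel_run_and_maf_floor(self, cfg):
        a, b = VariantKey("1", 100, "A", "G"), VariantKey("1", 200, "T", "C")
        panel = LdPanel("AFR")
        panel.set_maf(a, 0.0005)  # below the MAF floor: excluded in this panel
        panel.set_maf(b, 0.2)
        out = ld_prune_multi([self._rv(a, 1e-10), self._rv(b, 1e-8)], [panel], cfg)
        assert [rv.key for rv in out] == [b]

    def test_empty_panel_list_errors(self, cfg):
        with pytest.raises(ValueError):
            ld_prune_multi([], [], cfg)


class TestProxies:
    def _rv(self, key, p=1e-9):
        return RiskVariant(key=key, risk_allele=key.allele1, anchor_p=p)

    def test_ambiguous_variant_replaced_by_high_ld_proxy(self, cfg):
        amb = VariantKey("1", 100, "A", "T")
        proxy = VariantKey("1", 150, "A", "G")
        panel = LdPanel("EUR")
        panel.set_r2(amb, proxy, 0.85)
        trait = make_study("x", [stat(amb, "A", 0.1), stat(proxy, "A", 0.1)])
        out, subs = resolve_proxies([self._rv(amb)], [trait], [panel], cfg,
                                    proxy_candidates=[self._rv(proxy)])
        assert [rv.key for rv in out] == [proxy]
        assert subs[amb.vid][0] == proxy.vid and subs[amb.vid][1] == 0.85

    def test_cg_variant_without_qualifying_proxy_dropped(self, cfg):
        amb = VariantKey("1", 100, "C", "G")
        near = VariantKey("1", 150, "A", "G")
        panel = LdPanel("EUR")
        panel.set_r2(amb, near, 0.79)
        out, subs = resolve_proxies([self._rv(amb)], [], [panel], cfg,
                                    proxy_candidates=[self._rv(near)])
        assert out == [] and subs == {}

    def test_clean_variant_unchanged(self, cfg):
        v = VariantKey("1", 100, "A", "G")
        trait = make_study("x", [stat(v, "A", 0.1)])
        out, subs = resolve_proxies([self._rv(v)], [trait], [LdPanel("EUR")], cfg)
        assert [rv.key for rv in out] == [v] and subs == {}

    def test_high_missingness_triggers_replacement(self, cfg):
        v = VariantKey("1", 100, "A", "G")
        proxy = VariantKey("1", 150, "T", "C")
        traits = [make_study(f"t{i}", [stat(proxy, "T", 0.1)]) for i in range(5)]
        panel = LdPanel("EUR")
        panel.set_r2(v, proxy, 0.9)
        out, subs = resolve_proxies([self._rv(v)], traits, [panel], cfg,
                                    proxy_candidates=[self._rv(proxy)])
        assert [rv.key for rv in out] == [proxy]


class TestSelectTraits:
    def _rvs(self, keys):
        return [RiskVariant(k, k.allele1, 1e-9) for k in keys]

    def test_median_n_and_bonferroni_rules(self):
        cfg = PipelineConfig()
        keys = [VariantKey("1", 100 + i, "A", "G") for i in range(10)]
        rvs = self._rvs(keys)
        strong = make_study("strong", [stat(k, "A", 0.3, n=20000.0) for k in keys])
        underpowered = make_study("small", [stat(k, "A", 0.3, n=4999.0) for k in keys])
        # minimum p of 0.02 > 0.05/10: dropped
        weak = make_study("weak", [stat(k, "A", 0.12, p=0.02, n=20000.0) for k in keys])
        kept = select_traits([strong, underpowered, weak], rvs, cfg)
        assert [st.label for st in kept] == ["strong"]

    def test_correlated_pair_keeps_stronger_trait(self):
        cfg = PipelineConfig()
        rng = np.random.default_rng(1)
        keys = [VariantKey("1", 100 + i, "A", "G") for i in range(20)]
        rvs = self._rvs(keys)
        base = rng.normal(0, 2, 20)
        base[0] = 10.0
        se = 0.05

        def study(label, z):
            return make_study(label, [
                stat(k, "A", float(zi * se), se=se, n=20000.0) for k, zi in zip(keys, z)
            ])

        a = study("a", base)                       # max |z| = 10
        b = study("b", base * 0.8)                 # perfectly correlated, max |z| = 8
        kept = select_traits([a, b], rvs, cfg)
        assert [st.label for st in kept] == ["a"]


class TestAssemble:
    def test_sign_alignment_and_fill_rules(self):
        cfg = PipelineConfig()
        keys = [VariantKey("1", 100 + i, "A", "G") for i in range(4)]
        rvs = [RiskVariant(k, "G", 1e-9) for k in keys]  # risk allele is G
        # beta = -0.1 on A, se = 0.05 -> aligned z to G = +2
        tstats = [stat(k, "A", -0.1, se=0.05, n=20000.0) for k in keys[:3]]
        trait = make_study("t", tstats)
        panel = LdPanel("EUR")
        panel.set_r2(keys[3], keys[0], 0.6)  # proxy source for the missing cell
        m = assemble_matrix(rvs, [trait], [panel], cfg)
        prov = m.provenance
        assert prov.loc[keys[0].vid, "t"] == "observed"
        assert prov.loc[keys[3].vid, "t"].startswith("proxy:0.600")
        # pre-standardization aligned values were identical (+2 everywhere)
        center, scale = m.scaling_meta.loc["t", ["center", "scale"]]
        assert center == pytest.approx(2.0) and scale == 1.0

    def test_median_fill_when_no_proxy(self):
        cfg = PipelineConfig()
        keys = [VariantKey("1", 100 + i, "A", "G") for i in range(4)]
        rvs = [RiskVariant(k, "A", 1e-9) for k in keys]
        trait = make_study("t", [stat(k, "A", 0.05 * (i + 1), se=0.05, n=20000.0)
                                 for i, k in enumerate(keys[:3])])
        panel = LdPanel("EUR")
        panel.set_r2(keys[3], keys[0], 0.4)  # below the fill floor
        m = assemble_matrix(rvs, [trait], [panel], cfg)
        assert m.provenance.loc[keys[3].vid, "t"] == "median"
        raw = m.z.loc[keys[3].vid, "t"] * m.scaling_meta.loc["t", "scale"] + m.scaling_meta.loc["t", "center"]
        assert raw == pytest.approx(2.0)  # median of z = 1, 2, 3

    def test_alignment_involution(self, small_truth, small_studies):
        """Flipping every study's effect-allele encoding leaves the matrix unchanged."""
        from dataclasses import replace

        cfg = PipelineConfig()
        panels = [LdPanel(t) for t in ("AFR", "AMR", "EAS", "EUR", "SAS")]
        m1, _ = build_matrix(small_studies.t2d_studies, small_studies.t2d_anchor,
                             small_studies.trait_studies[:6], panels, cfg)

        def flip_study(st):
            return GwasStudy(st.trait_label, st.ancestry_tag, st.sex_tag,
                             [s.flipped() for s in st.stats])

        m2, _ = build_matrix([flip_study(s) for s in small_studies.t2d_studies],
                             flip_study(small_studies.t2d_anchor),
                             [flip_study(s) for s in small_studies.trait_studies[:6]],
                             panels, cfg)
        pd.testing.assert_frame_equal(m1.z, m2.z)

    def test_study_order_invariance(self, small_studies):
        cfg = PipelineConfig()
        panels = [LdPanel("EUR")]
        m1, _ = build_matrix(small_studies.t2d_studies, small_studies.t2d_anchor,
                             small_studies.trait_studies[:6], panels, cfg)
        m2, _ = build_matrix(list(reversed(small_studies.t2d_studies)), small_studies.t2d_anchor,
                             list(reversed(small_studies.trait_studies[:6])), panels, cfg)
        pd.testing.assert_frame_equal(m1.z.sort_index(axis=1), m2.z.sort_index(axis=1))
        assert set(m1.z.columns) == set(m2.z.columns)
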