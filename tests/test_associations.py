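"""Phenotype preparation, ancestry classification, regressions, meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from t2dclust.associations import (
    AssociationResult,
    bonferroni_threshold,
    classify_ancestry,
    fit_association,
    prepare_phenotypes,
    random_effects_meta,
    sex_interaction,
)
from t2dclust.gwas_io import CohortTable
from t2dclust.pps import PartitionedScoreMatrix
from t2dclust.synthetic_data import generate_cohort, make_planted_truth


def scores_from(values, index, cluster="cluster1"):
    raw = pd.DataFrame({cluster: values}, index=index)
    std = (raw - raw.mean()) / raw.std(ddof=0)
    return PartitionedScoreMatrix(raw=raw, standardized=std, variant_lists={})


@pytest.fixture(scope="module")
def pheno_cohort():
    truth = make_planted_truth(K_true=2, n_variants=40, n_traits=12, seed=21,
                               lab_effects={"ldl": np.array([0.1, 0.0]),
                                            "triglycerides": np.array([0.0, 0.1]),
                                            "total_cholesterol": np.array([0.0, 0.0]),
                                            "hdl": np.array([0.0, 0.0])})
    return generate_cohort(truth, n=4000, ancestry_mix={"EUR": 0.6, "EAS": 0.4}, seed=8)


class TestClassifyAncestry:
    def _reference(self, n_per_group=300, seed=0):
        rng = np.random.default_rng(seed)
        frames, labels = [], []
        for gi, g in enumerate(("EUR", "EAS", "AFR")):
            m = np.zeros(10)
            m[gi] = 6.0
            pcs = m + rng.normal(0, 0.4, size=(n_per_group, 10))
            frames.append(pd.DataFrame(pcs, columns=[f"PC{i+1}" for i in range(10)]))
            labels += [g] * n_per_group
        ref = pd.concat(frames, ignore_index=True)
        return ref, pd.Series(labels)

    def test_well_separated_groups_classified_correctly(self):
        ref, labels = self._reference()
        # hold out every third sample
        test_idx = ref.index[::3]
        train_idx = ref.index.difference(test_idx)
        assignments, _ = classify_ancestry(ref.loc[test_idx], ref.loc[train_idx],
                                           labels.loc[train_idx], min_group_n=1, seed=1)
        correct = sum(a.label == labels.loc[int(a.iid)] for a in assignments)
        assert correct / len(assignments) >= 0.95

    def test_low_probability_is_unclassified(self):
        ref, labels = self._reference()
        midpoint = pd.DataFrame([np.full(10, 2.0)], columns=ref.columns)
        assignments, _ = classify_ancestry(midpoint, ref, labels, min_group_n=1, seed=1)
        assert max(assignments[0].probabilities.values()) < 0.5
        assert assignments[0].label == "unclassified"

    def test_small_groups_excluded(self):
        ref, labels = self._reference()
        assignments, excluded = classify_ancestry(ref.iloc[:100], ref, labels,
                                                  min_group_n=500, seed=1)
        assert excluded  # every classified group here has < 500 members

    def test_pc_dimension_mismatch(self):
        ref, labels = self._reference()
        with pytest.raises(ValueError, match="dimension"):
            classify_ancestry(ref.iloc[:5, :5], ref, labels)


class TestPreparePhenotypes:
    def test_control_exclusions(self, pheno_cohort):
        pheno, log = prepare_phenotypes(pheno_cohort)
        df = pheno_cohort.samples
        young_controls = (df["t2d_status"] == 0) & (df["age"] < 30)
        assert pheno.loc[young_controls, "t2d_analysis"].isna().all()
        high_a1c = (df["t2d_status"] == 0) & (df["hba1c_max"] >= 6.5)
        assert pheno.loc[high_a1c, "t2d_analysis"].isna().all()
        cases = df["t2d_status"] == 1
        assert (pheno.loc[cases, "t2d_analysis"] == 1).all()

    def test_lipid_medication_divisors(self):
        samples = pd.DataFrame({
            "age": [50.0, 50.0], "sex": ["female", "male"],
            "t2d_status": [0, 0], "hba1c_max": [5.0, 5.0], "bmi": [25.0, 25.0],
            "lipid_med": [1, 0],
            "lab_total_cholesterol": [160.0, 160.0],
            "lab_ldl": [70.0, 70.0],
            "lab_triglycerides": [85.0, 85.0],
            "lab_hdl": [50.0, 50.0],
        }, index=pd.Index(["I1", "I2"], name="iid"))
        cohort = CohortTable(samples, pd.DataFrame(index=samples.index), {}, {})
        pheno, _ = prepare_phenotypes(cohort)
        assert pheno.loc["I1", "lab_total_cholesterol"] == pytest.approx(200.0)
        assert pheno.loc["I1", "lab_ldl"] == pytest.approx(100.0)
        assert pheno.loc["I1", "lab_triglycerides"] == pytest.approx(100.0)
        assert pheno.loc["I1", "lab_hdl"] == 50.0      # HDL never adjusted
        assert pheno.loc["I2", "lab_ldl"] == 70.0      # off medication: unchanged

    def test_log_transforms_and_negative_lab_error(self):
        samples = pd.DataFrame({
            "age": [40.0], "sex": ["female"], "t2d_status": [0], "hba1c_max": [5.0],
            "bmi": [30.0], "lipid_med": [0], "lab_triglycerides": [100.0],
        }, index=pd.Index(["I1"], name="iid"))
        cohort = CohortTable(samples, pd.DataFrame(index=samples.index), {}, {})
        pheno, _ = prepare_phenotypes(cohort)
        assert pheno.loc["I1", "log_bmi"] == pytest.approx(np.log(30.0))
        assert pheno.loc["I1", "log_triglycerides"] == pytest.approx(np.log(100.0))
        samples["lab_triglycerides"] = [-1.0]
        with pytest.raises(ValueError, match="negative lab"):
            prepare_phenotypes(CohortTable(samples, pd.DataFrame(index=samples.index), {}, {}))


class TestFitAssociation:
    def test_planted_continuous_effect_recovered(self, pheno_cohort):
        """The planted 0.1-per-SD LDL effect of cluster 1 comes back within
        2 SEs (outcome standardized, so expected slope is 0.1 / sd(lab))."""
        truth = make_planted_truth(K_true=2, n_variants=40, n_traits=12, seed=21,
                                   lab_effects={"ldl": np.array([0.1, 0.0])})
        # no medication adjustment: the generator's labs are as-measured
        pheno, _ = prepare_phenotypes(pheno_cohort, adjust_lipids=False)
        raw = pheno_cohort.dosages.to_numpy() @ truth.W_true
        scores = PartitionedScoreMatrix(
            raw=pd.DataFrame(raw, index=pheno.index, columns=["cluster1", "cluster2"]),
            standardized=pd.DataFrame(
                (raw - raw.mean(0)) / raw.std(0), index=pheno.index,
                columns=["cluster1", "cluster2"]),
            variant_lists={})
        res = fit_association(scores, "cluster1", "lab_ldl", pheno)
        expected = 0.1 / np.sqrt(0.1**2 + 1.0)
        assert abs(res.effect - expected) < 2 * res.se

    def test_binary_min_cases_rule(self, pheno_cohort):
        pheno, _ = prepare_phenotypes(pheno_cohort)
        pheno["outcome_rare"] = 0.0
        pheno.iloc[:499, pheno.columns.get_loc("outcome_rare")] = 1.0
        scores = scores_from(np.random.default_rng(1).normal(size=len(pheno)), pheno.index)
        res = fit_association(scores, "cluster1", "outcome_rare", pheno)
        assert res.flagged and "fewer than 500" in res.skip_reason

    def test_per_sd_convention_scale_invariance(self, pheno_cohort):
        pheno, _ = prepare_phenotypes(pheno_cohort)
        vals = np.random.default_rng(2).normal(size=len(pheno))
        res1 = fit_association(scores_from(vals, pheno.index), "cluster1", "lab_ldl", pheno)
        res2 = fit_association(scores_from(vals * 2.0, pheno.index), "cluster1", "lab_ldl", pheno)
        assert res1.effect == pytest.approx(res2.effect, rel=1e-9)
        assert res1.se == pytest.approx(res2.se, rel=1e-9)


class TestSexInteraction:
    def test_stratified_effects_returned(self, pheno_cohort):
        pheno, _ = prepare_phenotypes(pheno_cohort)
        scores = scores_from(np.random.default_rng(3).normal(size=len(pheno)), pheno.index)
        res = sex_interaction(scores, "cluster1", "lab_ldl", pheno)
        assert res.effect_female.stratum == "female"
        assert res.effect_male.stratum == "male"
        assert 0 <= res.p_interaction <= 1

    def test_single_sex_cohort_errors(self, pheno_cohort):
        pheno, _ = prepare_phenotypes(pheno_cohort)
        females = pheno[pheno["sex"] == "female"]
        scores = scores_from(np.zeros(len(females)), females.index)
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction(scores, "cluster1", "lab_ldl", females)

    def test_planted_sex_difference_detected(self):
        rng = np.random.default_rng(7)
        n = 50000
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        pps = rng.normal(size=n)
        beta_f, beta_m = 0.06, 0.03
        y = np.where(sex == "female", beta_f, beta_m) * pps + rng.normal(size=n)
        pheno = pd.DataFrame({"sex": sex, "age": 50.0, "ancestry_label": "EUR", "y": y},
                             index=pd.Index([f"I{i}" for i in range(n)], name="iid"))
        scores = scores_from(pps, pheno.index)
        res = sex_interaction(scores, "cluster1", "y", pheno)
        assert res.p_interaction < 0.05
        assert res.effect_female.effect > res.effect_male.effect


class TestMeta:
    def _res(self, beta, se, flagged=False):
        return AssociationResult(cluster="c", outcome="o", effect=beta, se=se,
                                 p=0.5, n=100, binary=False, covariates=(),
                                 flagged=flagged)

    def test_homogeneous_pair_collapses_to_fixed_effects(self):
        meta = random_effects_meta([self._res(0.2, 0.1), self._res(0.2, 0.1)])
        assert meta.beta == pytest.approx(0.2)
        assert meta.tau2 == 0.0
        assert meta.se == pytest.approx(0.1 / np.sqrt(2))

    def test_dersimonian_laird_oracle_triple(self):
        # independent closed-form computation of the DL estimator
        betas = np.array([0.10, 0.30, 0.50])
        ses = np.array([0.10, 0.10, 0.20])
        w = 1 / ses**2
        b_fe = np.sum(w * betas) / np.sum(w)
        Q = np.sum(w * (betas - b_fe) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - 2) / c)
        w_star = 1 / (ses**2 + tau2)
        b_re = np.sum(w_star * betas) / np.sum(w_star)
        se_re = np.sum(w_star) ** -0.5
        meta = random_effects_meta([self._res(b, s) for b, s in zip(betas, ses)])
        assert meta.beta == pytest.approx(b_re, abs=1e-12)
        assert meta.se == pytest.approx(se_re, abs=1e-12)
        assert meta.tau2 == pytest.approx(tau2, abs=1e-12)

    def test_single_cohort_passthrough_and_flag_exclusion(self):
        meta = random_effects_meta([self._res(0.3, 0.05), self._res(9.9, 0.01, flagged=True)])
        assert meta.beta == 0.3 and meta.tau2 == 0.0 and meta.n == 1

    def test_random_effects_se_not_below_fixed(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            betas = rng.normal(0, 0.3, 4)
            ses = rng.uniform(0.05, 0.2, 4)
            w = 1 / ses**2
            se_fe = np.sum(w) ** -0.5
            meta = random_effects_meta([self._res(b, s) for b, s in zip(betas, ses)])
            assert meta.se >= se_fe - 1e-12


class TestBonferroni:
    def test_paper_rule_arithmetic(self):
        assert bonferroni_threshold(12, 4) == pytest.approx(0.05 / 48)
        assert bonferroni_threshold(1, 1) == 0.05
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 4)
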