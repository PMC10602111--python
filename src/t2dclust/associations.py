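"""Cluster pPS - phenotype association analyses.

Covers genetic-ancestry classification from principal components, phenotype
preparation (control exclusions, lipid-medication adjustment, log
transforms), linear/logistic regressions of outcomes on standardized pPS,
sex-stratified and sex-interaction models, DerSimonian-Laird random-effects
meta-analysis across cohorts, and the Bonferroni rule for discovery
outcomes.

Effect-size convention: all effects are per one standard deviation of the
cluster pPS; continuous outcomes are normalized to a standard normal scale
before fitting, binary outcomes are reported as log-odds ratios (with OR
alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .gwas_io import CohortTable, logger
from .pps import MetaAnalysisResult, PartitionedScoreMatrix

ANCESTRY_GROUPS = ("AFR", "AMR", "EAS", "EUR", "MID", "SAS")

DEFAULT_LOG_TRANSFORM = ("bmi", "triglycerides")
LIPID_ADJUST_DIVISORS = {"total_cholesterol": 0.8, "ldl": 0.7, "triglycerides": 0.85}


@dataclass
class AncestryAssignment:
    iid: str
    label: str                       # group or "unclassified"
    probabilities: dict[str, float]


@dataclass
class AssociationResult:
    cluster: str
    outcome: str
    effect: float                    # beta per SD pPS, or log-OR per SD pPS
    se: float
    p: float
    n: int
    binary: bool
    covariates: tuple[str, ...]
    stratum: str = "all"
    cohort: str = ""
    flagged: bool = False
    skip_reason: str | None = None

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.effect)) if self.binary else None


@dataclass
class InteractionResult:
    cluster: str
    outcome: str
    p_interaction: float
    effect_female: AssociationResult
    effect_male: AssociationResult


def classify_ancestry(
    cohort_pcs: pd.DataFrame,
    reference_pcs: pd.DataFrame,
    reference_labels: pd.Series,
    min_group_n: int = 500,
    min_probability: float = 0.5,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[list[AncestryAssignment], list[str]]:
    """Label cohort individuals by continental ancestry from PCs.

    A random-forest classifier is trained on labeled reference PC
    coordinates; an individual whose maximum group probability falls below
    ``min_probability`` stays "unclassified". Groups ending up with fewer
    than ``min_group_n`` classified members are returned as an exclusion
    list for downstream analyses.
    """
    if reference_labels.nunique() < 2:
        raise ValueError("reference must contain at least two labeled groups")
    if list(cohort_pcs.columns) != list(reference_pcs.columns):
        raise ValueError("PC dimension mismatch between cohort and reference")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(reference_pcs.to_numpy(), reference_labels.to_numpy())
    proba = clf.predict_proba(cohort_pcs.to_numpy())
    classes = list(clf.classes_)
    assignments = []
    for iid, row in zip(cohort_pcs.index, proba):
        probs = dict(zip(classes, (float(x) for x in row)))
        best = classes[int(np.argmax(row))]
        label = best if probs[best] >= min_probability else "unclassified"
        assignments.append(AncestryAssignment(iid=str(iid), label=label, probabilities=probs))
    counts = pd.Series([a.label for a in assignments]).value_counts()
    excluded = sorted(
        g for g in counts.index if g != "unclassified" and counts[g] < min_group_n
    )
    if excluded:
        logger.info("ancestry groups excluded for size < %d: %s", min_group_n, excluded)
    return assignments, excluded


def prepare_phenotypes(
    cohort: CohortTable,
    transform_list: tuple[str, ...] = DEFAULT_LOG_TRANSFORM,
    adjust_lipids: bool = True,
    control_min_age: float = 30.0,
    control_max_hba1c: float = 6.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Analysis-ready phenotype table with an edit log.

    Controls (t2d_status == 0) younger than 30 or with any HbA1c >= 6.5%
    are excluded from the case/control analysis (``t2d_analysis`` is set to
    NaN for them; cases are untouched). On lipid-lowering medication, total
    cholesterol is divided by 0.8, LDL by 0.7, triglycerides by 0.85 (HDL
    unadjusted). Skewed traits in ``transform_list`` are log-transformed.
    """
    df = cohort.samples.copy()
    log: list[dict] = []
    lab_cols = {c.removeprefix("lab_"): c for c in df.columns if c.startswith("lab_")}
    for name, col in lab_cols.items():
        if (df[col].dropna() < 0).any():
            bad = df.index[df[col] < 0][0]
            raise ValueError(f"negative lab value in {col} (e.g. individual {bad})")

    df["t2d_analysis"] = df.get("t2d_status", pd.Series(np.nan, index=df.index)).astype(float)
    is_control = df["t2d_analysis"] == 0
    too_young = is_control & (df["age"] < control_min_age)
    high_a1c = is_control & (df.get("hba1c_max", pd.Series(np.nan, index=df.index)) >= control_max_hba1c)
    for iid in df.index[too_young | high_a1c]:
        log.append({"iid": iid, "edit": "control_excluded"})
    df.loc[too_young | high_a1c, "t2d_analysis"] = np.nan

    if adjust_lipids and "lipid_med" in df.columns:
        on_med = df["lipid_med"].astype(bool)
        for name, divisor in LIPID_ADJUST_DIVISORS.items():
            col = lab_cols.get(name)
            if col is None:
                continue
            df.loc[on_med, col] = df.loc[on_med, col] / divisor
            for iid in df.index[on_med & df[col].notna()]:
                log.append({"iid": iid, "edit": f"lipid_adjusted:{name}"})

    for trait in transform_list:
        col = "bmi" if trait == "bmi" else lab_cols.get(trait, trait if trait in df.columns else None)
        if col is None or col not in df.columns:
            continue
        vals = df[col]
        if (vals.dropna() <= 0).any():
            raise ValueError(f"cannot log-transform non-positive values in {col}")
        df[f"log_{trait}"] = np.log(vals)
    return df, log


def _design(
    pheno: pd.DataFrame,
    pps_col: pd.Series,
    covariates: tuple[str, ...],
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    X = pd.DataFrame({"pps": pps_col})
    for cov in covariates:
        if cov == "sex":
            X["sex_male"] = (pheno["sex"] == "male").astype(float)
        elif cov == "ancestry":
            dummies = pd.get_dummies(pheno["ancestry_label"], prefix="anc", drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
        else:
            X[cov] = pd.to_numeric(pheno[cov], errors="coerce")
    if extra is not None:
        X = pd.concat([X, extra], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_association(
    scores: PartitionedScoreMatrix,
    cluster: str,
    outcome: str,
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "ancestry"),
    stratum: str = "all",
    min_cases: int = 500,
    cohort_label: str = "",
) -> AssociationResult:
    """Regress one outcome on one cluster's standardized pPS.

    Binary outcomes (two unique values) use logistic regression and report
    log-OR per SD of pPS; continuous outcomes are standardized to SD units
    and use linear regression. Binary outcomes with fewer than ``min_cases``
    cases are skipped (flagged result); non-convergence or separation flags
    the result so meta-analysis can exclude it.
    """
    data = pheno.copy()
    data["__pps"] = scores.standardized[cluster]
    if stratum in ("female", "male"):
        data = data[data["sex"] == stratum]
        covariates = tuple(c for c in covariates if c != "sex")
    y = pd.to_numeric(data[outcome], errors="coerce")
    mask = y.notna() & data["__pps"].notna()
    for cov in covariates:
        if cov in ("sex", "ancestry"):
            continue
        mask &= pd.to_numeric(data[cov], errors="coerce").notna()
    data, y = data[mask], y[mask]

    uniq = set(y.unique())
    binary = uniq <= {0.0, 1.0}
    n = len(y)

    def _skipped(reason: str) -> AssociationResult:
        return AssociationResult(cluster=cluster, outcome=outcome, effect=np.nan,
                                 se=np.nan, p=np.nan, n=n, binary=binary,
                                 covariates=covariates, stratum=stratum,
                                 cohort=cohort_label, flagged=True, skip_reason=reason)

    if n == 0:
        return _skipped("no observations")
    if binary:
        n_cases = int(y.sum())
        if n_cases < min_cases or (n - n_cases) < min_cases:
            return _skipped(f"fewer than {min_cases} cases or controls ({n_cases}/{n - n_cases})")
    X = _design(data, data["__pps"], covariates)
    try:
        if binary:
            fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                return _skipped("logistic model did not converge")
        else:
            y_std = (y - y.mean()) / y.std(ddof=0)
            fit = sm.OLS(y_std.to_numpy(), X.to_numpy()).fit()
    except (np.linalg.LinAlgError, PerfectSeparationError):
        return _skipped("model fit failed")
    i = list(X.columns).index("pps")
    return AssociationResult(
        cluster=cluster, outcome=outcome, effect=float(fit.params[i]),
        se=float(fit.bse[i]), p=float(fit.pvalues[i]), n=n, binary=binary,
        covariates=covariates, stratum=stratum, cohort=cohort_label,
    )


def sex_interaction(
    scores: PartitionedScoreMatrix,
    cluster: str,
    outcome: str,
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "ancestry"),
    cohort_label: str = "",
) -> InteractionResult:
    """Sex-by-pPS interaction model plus per-sex stratified fits."""
    sexes = set(pheno["sex"].dropna().unique())
    if not {"female", "male"} <= sexes:
        raise ValueError("both sexes must be present for an interaction model")
    data = pheno.copy()
    data["__pps"] = scores.standardized[cluster]
    y = pd.to_numeric(data[outcome], errors="coerce")
    mask = y.notna() & data["__pps"].notna()
    for cov in covariates:
        if cov in ("sex", "ancestry"):
            continue
        mask &= pd.to_numeric(data[cov], errors="coerce").notna()
    data, y = data[mask], y[mask]
    sex_male = (data["sex"] == "male").astype(float)
    extra = pd.DataFrame({"sex_male": sex_male, "pps_x_male": data["__pps"] * sex_male})
    X = _design(data, data["__pps"], tuple(c for c in covariates if c != "sex"), extra=extra)
    binary = set(y.unique()) <= {0.0, 1.0}
    if binary:
        fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
    else:
        y_std = (y - y.mean()) / y.std(ddof=0)
        fit = sm.OLS(y_std.to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index("pps_x_male")
    p_int = float(fit.pvalues[i])
    strat = {
        s: fit_association(scores, cluster, outcome, pheno, covariates=covariates,
                           stratum=s, min_cases=0, cohort_label=cohort_label)
        for s in ("female", "male")
    }
    return InteractionResult(cluster=cluster, outcome=outcome, p_interaction=p_int,
                             effect_female=strat["female"], effect_male=strat["male"])


def random_effects_meta(results: list[AssociationResult]) -> MetaAnalysisResult:
    """DerSimonian-Laird random-effects pool of per-cohort associations.

    Flagged results are excluded. With a single usable cohort the result
    passes through with tau^2 = 0; homogeneous inputs collapse to the
    fixed-effects answer.
    """
    usable = [r for r in results if not r.flagged]
    if not usable:
        raise ValueError("no non-flagged cohort results to pool")
    betas = np.array([r.effect for r in usable])
    ses = np.array([r.se for r in usable])
    w = 1.0 / ses**2
    beta_fe = np.sum(w * betas) / np.sum(w)
    if len(usable) == 1:
        r = usable[0]
        return MetaAnalysisResult(beta=r.effect, se=r.se, p=r.p, n=1, tau2=0.0,
                                  method="DL-random")
    Q = float(np.sum(w * (betas - beta_fe) ** 2))
    df = len(usable) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    p = float(2.0 * sps.norm.sf(abs(beta / se)))
    return MetaAnalysisResult(beta=beta, se=se, p=p, n=len(usable), tau2=tau2,
                              method="DL-random")


def bonferroni_threshold(n_clusters: int, n_outcomes: int) -> float:
    """Discovery-outcome significance level 0.05 / (K x N).

    Applies to discovery outcomes only; validation traits already used in
    the clustering are tested without multiplicity correction.
    """
    if n_clusters < 1 or n_outcomes < 1:
        raise ValueError("cluster and outcome counts must be >= 1")
    return 0.05 / (n_clusters * n_outcomes)


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "cluster": r.cluster, "outcome": r.outcome, "stratum": r.stratum,
            "cohort": r.cohort, "effect": r.effect, "se": r.se, "p": r.p,
            "n": r.n, "or": r.odds_ratio, "flagged": r.flagged,
            "skip_reason": r.skip_reason or "",
        })
    return pd.DataFrame(rows)
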