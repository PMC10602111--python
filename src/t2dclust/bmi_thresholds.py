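"""Ancestry-equivalent BMI thresholds for T2D risk.

A logistic model of T2D status on log(BMI), age, sex, and ancestry-group
indicators (optionally plus standardized cluster pPS) yields each group's
predicted T2D probability as a function of BMI. The reference risk is the
mean predicted probability over the reference group's individuals with BMI
set to the reference value (g-computation, default EUR at 30 kg/m^2); each
target group's equivalent BMI is the value at which its mean predicted
probability matches that reference risk, found by a monotone
one-dimensional root search in log BMI. Confidence intervals come from a
nonparametric bootstrap over individuals, and the gap-reduction summary
quantifies how much of the unadjusted threshold gap a pPS adjustment
closes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .pps import PartitionedScoreMatrix


@dataclass
class RiskModel:
    """Fitted logistic model of T2D on log-BMI, covariates, and pPS."""

    params: np.ndarray
    columns: list[str]
    cov: np.ndarray
    data: pd.DataFrame           # analysis rows: design covariates + group
    adjust_pps: tuple[str, ...]

    @property
    def log_bmi_coef(self) -> float:
        return float(self.params[self.columns.index("log_bmi")])


@dataclass
class BmiThresholdResult:
    group: str
    reference_group: str
    reference_bmi: float
    equivalent_bmi: float
    ci: tuple[float, float] | None
    adjusted_for: tuple[str, ...]
    reference_risk: float


def _build_design(df: pd.DataFrame, groups: list[str]) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {
        "const": np.ones(len(df)),
        "log_bmi": df["log_bmi"].to_numpy(dtype=float),
        "age": df["age"].to_numpy(dtype=float),
        "sex_male": (df["sex"] == "male").to_numpy(dtype=float),
    }
    for g in groups[1:]:  # first group is the baseline level
        cols[f"anc_{g}"] = (df["ancestry_label"] == g).to_numpy(dtype=float)
    for c in df.columns:
        if c.startswith("pps_"):
            cols[c] = df[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


def fit_risk_model(
    pheno: pd.DataFrame,
    adjust_pps: tuple[str, ...] = (),
    scores: PartitionedScoreMatrix | None = None,
) -> RiskModel:
    """Fit T2D status ~ log(BMI) + age + sex + ancestry (+ standardized pPS).

    ``pheno`` must carry t2d status (``t2d_analysis`` from phenotype
    preparation, or raw ``t2d_status``), ``bmi``, ``age``, ``sex``, and
    ``ancestry_label``. The fitted log-BMI coefficient must be positive
    (risk monotone in BMI) for threshold solving downstream.
    """
    for col in ("bmi", "age", "sex", "ancestry_label"):
        if col not in pheno.columns:
            raise ValueError(f"required column {col!r} missing from phenotype table")
    status_col = "t2d_analysis" if "t2d_analysis" in pheno.columns else "t2d_status"
    if status_col not in pheno.columns:
        raise ValueError("t2d status column missing")
    df = pheno.copy()
    if adjust_pps:
        if scores is None:
            raise ValueError("scores required when adjust_pps is non-empty")
        for c in adjust_pps:
            df[f"pps_{c}"] = scores.standardized[c]
    df["log_bmi"] = np.log(pd.to_numeric(df["bmi"], errors="coerce"))
    keep = ["log_bmi", "age", "sex", "ancestry_label", status_col] + [
        c for c in df.columns if c.startswith("pps_")
    ]
    df = df[keep].dropna()
    y = df[status_col].astype(float).to_numpy()
    groups = sorted(df["ancestry_label"].unique())
    X, columns = _build_design(df, groups)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # surface diagnostics rather than a bare trace
        raise RuntimeError(f"risk model failed to converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("risk model did not converge")
    return RiskModel(params=np.asarray(fit.params), columns=columns,
                     cov=np.asarray(fit.cov_params()), data=df.rename(columns={status_col: "t2d"}),
                     adjust_pps=tuple(adjust_pps))


def _mean_risk_at_bmi(
    model: RiskModel, group: str, bmi: float, pps_reference: str = "cohort_mean"
) -> float:
    """g-computation: mean predicted probability over the group's observed
    covariate distribution with BMI set to ``bmi``.

    In a pPS-adjusted model the pPS covariates are held at the cohort grand
    mean for every group (``pps_reference="cohort_mean"``, the default):
    the between-group comparison is then made at equal genetic background,
    so risk differences mediated by the scores drop out of the equivalent
    threshold. ``"group_observed"`` instead averages over each group's own
    pPS distribution (which leaves mediated differences in place).
    """
    sub = model.data[model.data["ancestry_label"] == group]
    if sub.empty:
        raise ValueError(f"group {group} absent from the fitted model data")
    groups = [c.removeprefix("anc_") for c in model.columns if c.startswith("anc_")]
    baseline = sorted(set(model.data["ancestry_label"]))[0]
    sub = sub.assign(log_bmi=np.log(bmi))
    if pps_reference == "cohort_mean":
        for c in sub.columns:
            if c.startswith("pps_"):
                sub = sub.assign(**{c: float(model.data[c].mean())})
    elif pps_reference != "group_observed":
        raise ValueError(f"unknown pps_reference {pps_reference!r}")
    X, _ = _build_design(sub, [baseline] + groups)
    eta = X @ model.params
    return float(np.mean(1.0 / (1.0 + np.exp(-eta))))


def equivalent_bmi(
    model: RiskModel,
    target_group: str,
    reference_group: str = "EUR",
    reference_bmi: float = 30.0,
    n_boot: int = 500,
    seed: int = 0,
    bmi_bounds: tuple[float, float] | None = None,
    pps_reference: str = "cohort_mean",
    _with_ci: bool = True,
) -> BmiThresholdResult:
    """BMI at which the target group's mean predicted T2D risk equals the
    reference group's risk at the reference BMI.

    The root is solved in log BMI (unique because the fitted log-BMI
    coefficient is positive, asserted here) within ``bmi_bounds``
    (default one third to eight thirds of the reference BMI, i.e. 10-80
    kg/m^2 at the usual reference of 30). The percentile CI refits the
    model on ``n_boot`` resamples of individuals.
    """
    if model.log_bmi_coef <= 0:
        raise ValueError("fitted log-BMI coefficient must be positive for a unique root")
    if bmi_bounds is None:
        bmi_bounds = (reference_bmi / 3.0, reference_bmi * 8.0 / 3.0)
    ref_risk = _mean_risk_at_bmi(model, reference_group, reference_bmi, pps_reference)
    if target_group == reference_group:
        eq = reference_bmi
    else:
        lo, hi = bmi_bounds
        f = lambda logb: _mean_risk_at_bmi(model, target_group, float(np.exp(logb)),
                                           pps_reference) - ref_risk
        flo, fhi = f(np.log(lo)), f(np.log(hi))
        if flo * fhi > 0:
            raise ValueError(
                f"reference risk {ref_risk:.4f} unreachable for group {target_group} "
                f"within BMI {bmi_bounds}"
            )
        eq = float(np.exp(brentq(f, np.log(lo), np.log(hi), xtol=1e-10)))
    ci = None
    if _with_ci and n_boot > 0:
        ci = _bootstrap_ci(model, target_group, reference_group, reference_bmi,
                           n_boot, seed, bmi_bounds, pps_reference)
    return BmiThresholdResult(
        group=target_group, reference_group=reference_group,
        reference_bmi=reference_bmi, equivalent_bmi=eq, ci=ci,
        adjusted_for=model.adjust_pps, reference_risk=ref_risk,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _bootstrap_ci(
    model: RiskModel,
    target_group: str,
    reference_group: str,
    reference_bmi: float,
    n_boot: int,
    seed: int,
    bmi_bounds: tuple[float, float],
    pps_reference: str,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI for the equivalent BMI.

    The design matrix is built once; each resample refits the logistic
    model and re-solves the threshold. A resample is discarded if the fit
    fails, the log-BMI coefficient is non-positive, a group is absent, or
    the root leaves the BMI bounds; the CI is reported only when at least
    half the resamples (and no fewer than 10) survive.
    """
    df = model.data
    groups = sorted(df["ancestry_label"].unique())
    X, columns = _build_design(df, groups)
    y = df["t2d"].to_numpy(dtype=float)
    j_bmi = columns.index("log_bmi")
    j_pps = [j for j, c in enumerate(columns) if c.startswith("pps_")]
    is_ref = (df["ancestry_label"] == reference_group).to_numpy()
    is_tgt = (df["ancestry_label"] == target_group).to_numpy()
    lo, hi = np.log(bmi_bounds[0]), np.log(bmi_bounds[1])
    rng = np.random.default_rng(seed)
    n = len(y)
    draws: list[float] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        rb, tb = is_ref[idx], is_tgt[idx]
        if not rb.any() or not tb.any():
            continue
        Xb, yb = X[idx], y[idx]
        try:
            fit = sm.Logit(yb, Xb).fit(disp=0, maxiter=100)
        except Exception:
            continue
        params = np.asarray(fit.params)
        if not np.all(np.isfinite(params)) or params[j_bmi] <= 0:
            continue
        Xe = Xb.copy()
        if pps_reference == "cohort_mean":
            for j in j_pps:
                Xe[:, j] = Xb[:, j].mean()
        # linear predictor with the BMI term stripped: eta(b) = base + beta*log b
        base = Xe @ params - params[j_bmi] * Xe[:, j_bmi]
        ref_risk = float(np.mean(_sigmoid(base[rb] + params[j_bmi] * np.log(reference_bmi))))
        if target_group == reference_group:
            draws.append(reference_bmi)
            continue
        bt = base[tb]

        def f(logb):
            return float(np.mean(_sigmoid(bt + params[j_bmi] * logb))) - ref_risk

        if f(lo) * f(hi) > 0:
            continue
        draws.append(float(np.exp(brentq(f, lo, hi, xtol=1e-8))))
    if len(draws) >= max(10, n_boot // 2):
        return float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5))
    return None


def gap_reduction(unadjusted: BmiThresholdResult, adjusted: BmiThresholdResult) -> tuple[float, float]:
    """How much of the threshold gap the pPS adjustment closes, in percent.

    reduction = 100 * (adjusted - unadjusted) / (reference_bmi - unadjusted);
    returned raw and rounded to the nearest 5 points.
    """
    if unadjusted.group != adjusted.group or unadjusted.reference_group != adjusted.reference_group:
        raise ValueError("results must compare the same target and reference groups")
    gap = unadjusted.reference_bmi - unadjusted.equivalent_bmi
    if gap == 0:
        raise ValueError("unadjusted gap is zero; reduction undefined")
    raw = 100.0 * (adjusted.equivalent_bmi - unadjusted.equivalent_bmi) / gap
    return raw, 5.0 * round(raw / 5.0)
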