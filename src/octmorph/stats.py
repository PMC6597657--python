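"""Cohort-level statistics: percent-of-control normalisation, linear
mixed-model group comparison on two-eye data, Bonferroni correction and
Pearson correlations.

The group comparison fits, separately for each parameter,

    parameter ~ group + eye + age

with a random intercept per participant (REML), so the two eyes of one
participant are treated as repeated measures. The group effect is reported
as an F statistic (the squared Wald t of the single group contrast) with
containment denominator degrees of freedom: participants minus the three
between-participant fixed-effect columns (intercept, group, age). A t-test
on participant means is offered as a simpler alternative path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PercentOfControl:
    parameter: str
    per_eye_pct: np.ndarray
    mean_pct: float
    sd_pct: float


def percent_of_control(case_values, control_mean: float,
                       parameter: str = "") -> PercentOfControl:
    """Express each per-eye value as a percentage of the control-group mean.

    Raises on a zero control mean, naming the parameter.
    """
    if control_mean == 0:
        raise ValueError(f"control mean is zero for parameter {parameter!r}")
    vals = 100.0 * np.asarray(case_values, dtype=float) / control_mean
    return PercentOfControl(parameter, vals, float(np.mean(vals)),
                            float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)


@dataclass
class GroupComparison:
    parameter: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    f_stat: float
    p_value: float
    df_num: int
    df_den: float
    p_adjusted: float | None = None
    downgraded: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p value outside [0, 1]")


def fit_group_lmm(cohort: pd.DataFrame, parameter: str,
                  method: str = "lmm") -> GroupComparison:
    """Compare case vs control eyes for one parameter.

    ``method='lmm'`` fits the mixed model described in the module
    docstring; ``method='ttest'`` runs Welch's t-test on participant means
    (the simpler path some summary tables use). Eyes with a missing value
    are dropped listwise for this parameter. A singular or non-converged
    mixed fit falls back to ordinary least squares and is flagged
    ``downgraded``.
    """
    import statsmodels.formula.api as smf

    df = cohort.dropna(subset=[parameter]).copy()
    if df.empty or df.groupby("group")["participant_id"].nunique().min() < 2:
        raise ValueError("need at least two participants per group")
    df["is_case"] = (df["group"] == "case").astype(float)

    by_group = df.groupby("group")[parameter]
    case_mean, case_sd = by_group.mean().get("case"), by_group.std().get("case")
    ctrl_mean, ctrl_sd = by_group.mean().get("control"), by_group.std().get("control")

    n_part = df["participant_id"].nunique()
    df_den = max(n_part - 3, 1)

    if method == "ttest":
        pm = df.groupby(["participant_id", "group"])[parameter].mean().reset_index()
        a = pm.loc[pm["group"] == "case", parameter]
        b = pm.loc[pm["group"] == "control", parameter]
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison(parameter, case_mean, case_sd, ctrl_mean, ctrl_sd,
                               float(t * t), float(p), 1, float(len(a) + len(b) - 2))
    if method != "lmm":
        raise ValueError("method must be 'lmm' or 'ttest'")

    formula = f"Q('{parameter}') ~ is_case + C(eye) + age_years"
    downgraded = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, df, groups=df["participant_id"]).fit(reml=True)
        coef, se = res.params["is_case"], res.bse["is_case"]
        if not np.isfinite(se) or se == 0:
            raise np.linalg.LinAlgError("degenerate standard error")
    except (np.linalg.LinAlgError, ValueError):
        res = smf.ols(formula, df).fit()
        coef, se = res.params["is_case"], res.bse["is_case"]
        downgraded = True

    f = float((coef / se) ** 2)
    p = float(sps.f.sf(f, 1, df_den))
    return GroupComparison(parameter, float(case_mean), float(case_sd),
                           float(ctrl_mean), float(ctrl_sd), f, p, 1,
                           float(df_den), downgraded=downgraded)


def bonferroni(pvals, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), m defaulting to the
    family size (the length of the list)."""
    pvals = list(pvals)
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p values must lie in [0, 1]")
    m = len(pvals) if m is None else m
    return [min(1.0, m * p) for p in pvals]


def correlate(cohort: pd.DataFrame, covariate: str, parameter: str):
    """Pearson correlation (r, two-sided p) over paired non-missing eyes."""
    df = cohort.dropna(subset=[covariate, parameter])
    if len(df) < 3:
        raise ValueError("need at least three paired values")
    x, y = df[covariate].to_numpy(float), df[parameter].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_table(cohort: pd.DataFrame, parameters, method: str = "lmm",
                bonferroni_m: int | None = None) -> pd.DataFrame:
    """Per-parameter comparison table: case and control mean +/- SD, the
    group-effect F and p, and the Bonferroni-adjusted p."""
    rows = [fit_group_lmm(cohort, p, method=method) for p in parameters]
    padj = bonferroni([r.p_value for r in rows], m=bonferroni_m)
    for r, pa in zip(rows, padj):
        r.p_adjusted = pa
    return pd.DataFrame([{
        "parameter": r.parameter,
        "case_mean": r.case_mean, "case_sd": r.case_sd,
        "control_mean": r.control_mean, "control_sd": r.control_sd,
        "F": r.f_stat, "p": r.p_value, "p_adjusted": r.p_adjusted,
        "downgraded": r.downgraded,
    } for r in rows])


def percent_table(cohort: pd.DataFrame, parameters,
                  case_affected_only: bool = True) -> pd.DataFrame:
    """Percent-of-control summary per parameter (case eyes relative to the
    control-group mean)."""
    ctrl = cohort[cohort["group"] == "control"]
    case = cohort[cohort["group"] == "case"]
    if case_affected_only and "affected" in cohort:
        case = case[case["affected"]]
    rows = []
    for p in parameters:
        poc = percent_of_control(case[p].dropna(), ctrl[p].mean(), p)
        rows.append({"parameter": p, "mean_pct": poc.mean_pct, "sd_pct": poc.sd_pct})
    return pd.DataFrame(rows)
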