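"""Fixed-threshold diagnostic classification with exact binomial intervals.

Eyes are classified by a single-parameter threshold rule; affected eyes
are the positive class and control eyes the negative class (the eye, not
the participant, is the unit of analysis). Sensitivity, specificity and
the predictive values carry exact Clopper-Pearson 95% confidence
intervals (beta-quantile construction). ``optimal_threshold`` searches the
midpoint grid between observed values for the rule maximising Youden's
J = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta


@dataclass(frozen=True)
class DiagRule:
    """A fixed threshold rule: an eye is test-positive when its parameter
    is >= threshold (``ge_is_case``) or <= threshold (``le_is_case``).
    Ties at the threshold count as positive."""

    parameter: str
    threshold: float
    direction: str = "ge_is_case"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.direction not in ("ge_is_case", "le_is_case"):
            raise ValueError("direction must be 'ge_is_case' or 'le_is_case'")

    def positive(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v >= self.threshold if self.direction == "ge_is_case" \
            else v <= self.threshold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricCI:
    """A rate in percent with its exact 95% confidence interval."""
    value: float
    lower: float
    upper: float


@dataclass(frozen=True)
class DiagResult:
    counts: ConfusionCounts
    sensitivity: MetricCI | None
    specificity: MetricCI | None
    ppv: MetricCI | None
    npv: MetricCI | None


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for x successes out of n, as
    proportions; the lower bound is 0 at x=0 and the upper 1 at x=n."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lo, hi


def select_eyes(cohort: pd.DataFrame, parameter: str,
                control_eyes: str = "one") -> tuple[pd.Series, pd.Series, int]:
    """Positive-class (affected) and negative-class (control) eye values.

    ``control_eyes='one'`` keeps one eye per control participant (the
    right eye by convention, matching a one-eye-per-control analysis);
    ``'both'`` keeps both. Eyes missing the parameter are excluded and
    counted.
    """
    if control_eyes not in ("one", "both"):
        raise ValueError("control_eyes must be 'one' or 'both'")
    aff = cohort[(cohort["group"] == "case") & cohort.get("affected", True)]
    ctrl = cohort[cohort["group"] == "control"]
    if control_eyes == "one":
        ctrl = ctrl[ctrl["eye"] == "OD"]
    pos, neg = aff[parameter], ctrl[parameter]
    n_excluded = int(pos.isna().sum() + neg.isna().sum())
    return pos.dropna(), neg.dropna(), n_excluded


def apply_rule(cohort: pd.DataFrame, rule: DiagRule,
               control_eyes: str = "one") -> ConfusionCounts:
    """Confusion counts of a threshold rule over a cohort: affected eyes
    meeting the rule are true positives, control eyes meeting it false
    positives."""
    pos, neg, n_excluded = select_eyes(cohort, rule.parameter, control_eyes)
    tp = int(rule.positive(pos).sum())
    fp = int(rule.positive(neg).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=len(pos) - tp,
                           tn=len(neg) - fp, n_excluded=n_excluded)


def diagnostic_metrics(tp: int, fp: int, fn: int, tn: int,
                       alpha: float = 0.05) -> DiagResult:
    """Sensitivity, specificity, PPV and NPV (percent) with exact
    Clopper-Pearson intervals; a metric with an empty denominator is
    reported as None (undefined)."""
    counts = ConfusionCounts(tp, fp, fn, tn)

    def metric(x, n):
        if n == 0:
            return None
        lo, hi = clopper_pearson(x, n, alpha)
        return MetricCI(100.0 * x / n, 100.0 * lo, 100.0 * hi)

    return DiagResult(
        counts=counts,
        sensitivity=metric(tp, tp + fn),
        specificity=metric(tn, tn + fp),
        ppv=metric(tp, tp + fp),
        npv=metric(tn, tn + fn),
    )


def _significant_digits(value: float) -> int:
    """Number of significant digits of a decimal literal (tie-break:
    'rounder' thresholds have fewer)."""
    s = np.format_float_positional(value, trim="-")
    return len(s.replace("-", "").replace(".", "").lstrip("0").rstrip("0") or "0")


def optimal_threshold(cohort: pd.DataFrame, parameter: str,
                      direction: str = "ge_is_case",
                      extra_candidates=(), control_eyes: str = "one"
                      ) -> tuple[DiagRule, float]:
    """Youden-optimal threshold rule for one parameter.

    Candidates are the midpoints between consecutive distinct observed
    values (plus the observed extremes and any ``extra_candidates``). Ties
    on J are broken toward higher specificity, then toward the rounder
    value (fewer significant digits).
    """
    pos, neg, _ = select_eyes(cohort, parameter, control_eyes)
    values = np.sort(np.unique(np.concatenate([pos, neg])))
    if len(values) < 2:
        raise ValueError("all observed values identical; no threshold exists")
    grid = np.concatenate([values[:1], 0.5 * (values[:-1] + values[1:]),
                           values[-1:], np.asarray(extra_candidates, dtype=float)])

    best = None
    for thr in grid:
        rule = DiagRule(parameter, float(thr), direction)
        tp = int(rule.positive(pos).sum())
        fp = int(rule.positive(neg).sum())
        sens = tp / len(pos)
        spec = (len(neg) - fp) / len(neg)
        j = sens + spec - 1.0
        key = (j, spec, -_significant_digits(float(thr)))
        if best is None or key > best[0]:
            best = (key, rule, j)
    return best[1], float(best[2])


def counts_from_rates(rates_pct, max_n: int, decimals: int = 1
                      ) -> tuple[int, dict[float, int]]:
    """Recover confusion counts from printed rates sharing one denominator.

    Finds the smallest n <= max_n such that every rate in ``rates_pct``
    equals round(100 x / n, decimals) for exactly one integer x, and
    returns (n, {rate: x}). Raises when no denominator is consistent or
    when a rate is ambiguous at the smallest consistent n.
    """
    rates = [float(r) for r in np.atleast_1d(rates_pct)]
    if any(not 0.0 <= r <= 100.0 for r in rates):
        raise ValueError("rates must be percentages in [0, 100]")
    if max_n < 1:
        raise ValueError("max_n must be at least 1")
    for n in range(1, max_n + 1):
        matches = {r: [x for x in range(n + 1)
                       if round(100.0 * x / n, decimals) == round(r, decimals)]
                   for r in rates}
        if any(len(xs) == 0 for xs in matches.values()):
            continue
        ambiguous = {r: xs for r, xs in matches.items() if len(xs) > 1}
        if ambiguous:
            raise ValueError(f"ambiguous counts at denominator {n}: {ambiguous}")
        return n, {r: xs[0] for r, xs in matches.items()}
    raise ValueError(f"no denominator up to {max_n} reproduces rates {rates}")


def diagnostic_table(cohort: pd.DataFrame, rules, control_eyes: str = "one"
                     ) -> pd.DataFrame:
    """Apply a list of rules and tabulate accuracy with 95% CIs, one row
    per rule, columns ordered sensitivity / specificity / PPV / NPV."""
    rows = []
    for rule in rules:
        c = apply_rule(cohort, rule, control_eyes)
        res = diagnostic_metrics(c.tp, c.fp, c.fn, c.tn)
        row = {"parameter": rule.parameter, "threshold": rule.threshold,
               "direction": rule.direction,
               "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m = getattr(res, name)
            row[name] = None if m is None else m.value
            row[f"{name}_lci"] = None if m is None else m.lower
            row[f"{name}_uci"] = None if m is None else m.upper
        rows.append(row)
    return pd.DataFrame(rows)
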