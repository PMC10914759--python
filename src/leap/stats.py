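"""Descriptive and inferential statistics for the biosensor cohort.

Implements the percent-difference activity statistic, per-feature pooled
two-sample t-tests, the two-sample Hotelling T-squared test, exact
Clopper-Pearson binomial intervals, confusion-table classification metrics,
and triplicate classification precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantitation import LABEL_CANCER, feature_columns


@dataclass
class GroupComparison:
    feature: str
    mean_case: float
    mean_control: float
    percent_difference: float | None
    t_statistic: float
    p_value: float


@dataclass
class HotellingResult:
    t2: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float


@dataclass
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.successes / self.trials


@dataclass
class MetricsReport:
    """Sensitivity/specificity/NPV/PPV/accuracy with exact CIs.

    Metrics whose denominator is empty (e.g. PPV with no positive calls)
    are ``None`` — undefined, not zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    level: float = 0.95
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        pairs = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "ppv": (self.tp, self.tp + self.fp),
            "accuracy": (self.tp + self.tn, self.tp + self.fp + self.tn + self.fn),
        }
        for name, (x, n) in pairs.items():
            self.metrics[name] = (
                None if n == 0 else clopper_pearson(x, n, self.level)
            )

    def value(self, name: str) -> float | None:
        ci = self.metrics[name]
        return None if ci is None else ci.estimate


def percent_difference(case_values, control_values) -> float:
    """Activity decrease in cancer as a percent of the cancer-group mean.

    100 * (mean_control - mean_case) / mean_case; positive values mean
    decreased activity in the cancer group.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    mc = case.mean()
    if mc <= 0:
        raise ValueError("undefined denominator: cancer-group mean <= 0")
    return 100.0 * (control.mean() - mc) / mc


def timepoint_tests(
    features: pd.DataFrame,
    labels=None,
    equal_var: bool = True,
    alpha: float = 0.01,
):
    """Per-feature two-sample t-tests between cancer and control assays.

    Pooled-variance Student's t by default (``equal_var=False`` for Welch);
    two-sided p-values, no multiple-testing correction. Returns
    ``(comparisons, fraction_significant)`` where the fraction counts
    features with p <= alpha.
    """
    cols = feature_columns(features)
    if labels is None:
        labels = features["label"] == LABEL_CANCER
    labels = np.asarray(labels, dtype=bool)
    X = features[cols].to_numpy(dtype=float)
    case, control = X[labels], X[~labels]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each class needs >= 2 observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(case, control, axis=0, equal_var=equal_var)
    # zero pooled variance (identical constant groups): no evidence, t=0 p=1
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    out = []
    for j, name in enumerate(cols):
        mc, mn = float(case[:, j].mean()), float(control[:, j].mean())
        if mc > 0:
            pdiff = 100.0 * (mn - mc) / mc
        else:
            warnings.warn(f"{name}: cancer-group mean <= 0, percent difference undefined")
            pdiff = None
        out.append(GroupComparison(name, mc, mn, pdiff, float(t[j]), float(p[j])))
    frac = float(np.mean(p <= alpha))
    return out, frac


def hotelling_t2(x_case, x_control) -> HotellingResult:
    """Two-sample Hotelling T-squared test with pooled covariance.

    T2 = (n1*n2/(n1+n2)) d' S^-1 d; F = T2 (n1+n2-p-1)/((n1+n2-2) p) on
    (p, n1+n2-p-1) degrees of freedom; p-value from the F upper tail.
    """
    X1 = np.atleast_2d(np.asarray(x_case, dtype=float))
    X2 = np.atleast_2d(np.asarray(x_control, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions differ")
    n1, n2, p = len(X1), len(X2), X1.shape[1]
    if n1 + n2 - 2 < p:
        raise ValueError("too few samples for the feature count")
    d = X1.mean(axis=0) - X2.mean(axis=0)
    S = ((n1 - 1) * np.cov(X1, rowvar=False, ddof=1).reshape(p, p)
         + (n2 - 1) * np.cov(X2, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; reduce or decorrelate features"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    df1, df2 = p, n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return HotellingResult(t2, float(f_stat), df1, df2, min(max(p_value, 0.0), 1.0))


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial confidence interval from Beta-distribution quantiles."""
    x, n = int(successes), int(trials)
    if n < 1 or not 0 <= x <= n:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialCI(x, n, level, lower, upper)


def classification_metrics(truth, calls, level: float = 0.95) -> MetricsReport:
    """Confusion-table metrics with a Clopper-Pearson CI per metric."""
    y = np.asarray(truth, dtype=bool)
    c = np.asarray(calls, dtype=bool)
    if y.shape != c.shape:
        raise ValueError("truth and calls differ in length")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present in truth")
    tp = int((y & c).sum())
    fp = int((~y & c).sum())
    tn = int((~y & ~c).sum())
    fn = int((y & ~c).sum())
    return MetricsReport(tp, fp, tn, fn, level)


def balanced_accuracy(truth, calls) -> float:
    y = np.asarray(truth, dtype=bool)
    c = np.asarray(calls, dtype=bool)
    sens = (y & c).sum() / y.sum()
    spec = (~y & ~c).sum() / (~y).sum()
    return float((sens + spec) / 2)


def precision_from_replicates(calls_by_donor: dict) -> float:
    """Percent of triplicate donors whose three calls fully agree.

    ``calls_by_donor`` maps donor_id -> sequence of exactly 3 class calls.
    """
    if not calls_by_donor:
        raise ValueError("no triplicate donors supplied")
    concordant = 0
    for donor, calls in calls_by_donor.items():
        calls = list(calls)
        if len(calls) != 3:
            raise ValueError(f"donor {donor!r}: expected 3 calls, got {len(calls)}")
        concordant += len(set(bool(c) for c in calls)) == 1
    return 100.0 * concordant / len(calls_by_donor)


def per_call_precision(calls_by_donor: dict) -> float:
    """Percent of individual calls agreeing with their donor's majority call."""
    if not calls_by_donor:
        raise ValueError("no triplicate donors supplied")
    agree = total = 0
    for donor, calls in calls_by_donor.items():
        calls = [bool(c) for c in calls]
        if len(calls) != 3:
            raise ValueError(f"donor {donor!r}: expected 3 calls, got {len(calls)}")
        majority = sum(calls) >= 2
        agree += sum(c == majority for c in calls)
        total += 3
    return 100.0 * agree / total


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional; raw p-values are the default output)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
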