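"""Objective engagement classification and group-comparison statistics.

A univariate quadratic discriminant analysis (QDA) is fit to block-2
disengagement scores of the depressed and healthy-control groups.  With
class-specific Gaussians N(mu_g, sigma_g^2) and priors pi_g, the decision
boundary solves

    log[pi_MDD phi(x; mu_MDD, sigma_MDD)] = log[pi_HC phi(x; mu_HC, sigma_HC)]

a quadratic in x with (generically) two roots.  The operative cutoff is
the root above the healthy-control mean beyond which the depressed-class
posterior dominates; scores at or above the cutoff are labeled
"disengaged".  The module also provides the comparison statistics used to
characterize the resulting subgroups: the uncorrected Pearson chi-square
for contingency tables, and the unequal-variance t-test with the
Cochran–Cox weighted-critical-value approximation for continuous scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

ENGAGED = "engaged"
DISENGAGED = "disengaged"


class DegenerateModelError(ValueError):
    """Zero within-group variance or identical class distributions."""


class DegenerateTableError(ValueError):
    """A contingency table with an empty margin or a single category."""


@dataclass(frozen=True)
class EngagementModel:
    """Fitted univariate two-class QDA and its derived cutoff."""

    mean_hc: float
    sd_hc: float
    mean_mdd: float
    sd_mdd: float
    prior_hc: float
    prior_mdd: float
    cutoff: float
    roots: tuple[float, ...]

    def discriminant(self, x):
        """log[pi_MDD phi_MDD(x)] - log[pi_HC phi_HC(x)]; positive => MDD wins."""
        x = np.asarray(x, dtype=float)
        ll_mdd = (math.log(self.prior_mdd)
                  + stats.norm.logpdf(x, self.mean_mdd, self.sd_mdd))
        ll_hc = (math.log(self.prior_hc)
                 + stats.norm.logpdf(x, self.mean_hc, self.sd_hc))
        return ll_mdd - ll_hc


def _boundary_roots(mu1: float, s1: float, mu2: float, s2: float,
                    pi1: float, pi2: float) -> tuple[float, ...]:
    """Roots of log[pi2 phi2] - log[pi1 phi1] = 0 (1 = HC, 2 = MDD)."""
    a = 0.5 * (1.0 / s1**2 - 1.0 / s2**2)
    b = mu2 / s2**2 - mu1 / s1**2
    c = (0.5 * (mu1**2 / s1**2 - mu2**2 / s2**2)
         + math.log(pi2 / pi1) + math.log(s1 / s2))
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            raise DegenerateModelError("class distributions are identical: no boundary")
        return (-c / b,)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise DegenerateModelError(
            "discriminant boundary has no real root (one class dominates everywhere)")
    sq = math.sqrt(disc)
    r1 = (-b - sq) / (2.0 * a)
    r2 = (-b + sq) / (2.0 * a)
    return tuple(sorted((r1, r2)))


def fit_qda_1d(values_mdd: Sequence[float], values_hc: Sequence[float],
               priors: Optional[tuple[float, float]] = None) -> EngagementModel:
    """Fit the two-class univariate QDA on block-2 scores.

    Parameters
    ----------
    values_mdd, values_hc
        Block-2 disengagement scores per group (at least 2 each).
    priors
        Optional (prior_hc, prior_mdd).  Defaults to empirical class
        frequencies.  Group variances use the unbiased (n-1) estimator.
    """
    x_mdd = np.asarray(values_mdd, dtype=float)
    x_hc = np.asarray(values_hc, dtype=float)
    if x_mdd.size < 2 or x_hc.size < 2:
        raise DegenerateModelError("need at least 2 scores per group")
    mu_hc, sd_hc = float(x_hc.mean()), float(x_hc.std(ddof=1))
    mu_mdd, sd_mdd = float(x_mdd.mean()), float(x_mdd.std(ddof=1))
    if sd_hc == 0.0 or sd_mdd == 0.0:
        raise DegenerateModelError("zero within-group variance")
    if priors is None:
        n = x_mdd.size + x_hc.size
        pi_hc, pi_mdd = x_hc.size / n, x_mdd.size / n
    else:
        pi_hc, pi_mdd = priors
        if not math.isclose(pi_hc + pi_mdd, 1.0, abs_tol=1e-9):
            raise ValueError("priors must sum to 1")
    roots = _boundary_roots(mu_hc, sd_hc, mu_mdd, sd_mdd, pi_hc, pi_mdd)
    cutoff = _select_cutoff(roots, mu_hc, sd_hc, mu_mdd, sd_mdd, pi_hc, pi_mdd)
    return EngagementModel(mean_hc=mu_hc, sd_hc=sd_hc, mean_mdd=mu_mdd,
                           sd_mdd=sd_mdd, prior_hc=pi_hc, prior_mdd=pi_mdd,
                           cutoff=cutoff, roots=roots)


def _select_cutoff(roots, mu_hc, sd_hc, mu_mdd, sd_mdd, pi_hc, pi_mdd) -> float:
    """Pick the operative single threshold among the boundary roots.

    The rule mirrors the geometry of a disengaged tail: the cutoff is the
    root at which the depressed-class posterior takes over as scores
    increase, preferring a root above the healthy-control mean.
    """
    def disc(x):
        return (math.log(pi_mdd) + stats.norm.logpdf(x, mu_mdd, sd_mdd)
                - math.log(pi_hc) - stats.norm.logpdf(x, mu_hc, sd_hc))

    upward = []
    for r in roots:
        span = max(sd_hc, sd_mdd) * 1e-4
        if disc(r + span) > disc(r - span):
            upward.append(r)
    if not upward:
        raise DegenerateModelError(
            "no upward crossing: the depressed class never dominates above a threshold")
    above = [r for r in upward if r >= mu_hc]
    return above[0] if above else upward[-1]


def classify(values: Sequence[float], model: EngagementModel) -> list[str]:
    """Label scores: disengaged iff value >= cutoff (boundary ties disengaged)."""
    x = np.asarray(values, dtype=float)
    return [DISENGAGED if v >= model.cutoff else ENGAGED for v in x]


@dataclass(frozen=True)
class DiagnosticStats:
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int


def diagnostic_stats(labels: Sequence[str], true_groups: Sequence[str],
                     positive_label: str = DISENGAGED,
                     positive_group: str = "MDD",
                     ci_method: str = "wilson") -> DiagnosticStats:
    """Sensitivity/specificity of the labels against a reference grouping.

    Sensitivity is the fraction of the positive group (default MDD) given
    the positive label; specificity the fraction of the other group not
    given it.  95% CIs are Wilson score intervals by default
    (``ci_method="beta"`` switches to exact Clopper–Pearson).
    """
    labels = list(labels)
    groups = list(true_groups)
    if len(labels) != len(groups):
        raise ValueError("labels and true_groups differ in length")
    pos = [l for l, g in zip(labels, groups) if g == positive_group]
    neg = [l for l, g in zip(labels, groups) if g != positive_group]
    if not pos or not neg:
        raise DegenerateTableError("both groups must be non-empty")
    tp = sum(1 for l in pos if l == positive_label)
    tn = sum(1 for l in neg if l != positive_label)
    sens = tp / len(pos)
    spec = tn / len(neg)
    method = "wilson" if ci_method == "wilson" else "beta"
    sens_ci = proportion_confint(tp, len(pos), alpha=0.05, method=method)
    spec_ci = proportion_confint(tn, len(neg), alpha=0.05, method=method)
    return DiagnosticStats(sensitivity=sens, specificity=spec,
                           sensitivity_ci=tuple(map(float, sens_ci)),
                           specificity_ci=tuple(map(float, spec_ci)),
                           tp=tp, fn=len(pos) - tp, tn=tn, fp=len(neg) - tn)


def chisq_independence(table, correction: bool = False) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence on an r x c table.

    Yates continuity correction is off by default (the convention used for
    all reported comparisons); pass ``correction=True`` to enable it.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("need an r x c table with r, c >= 2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal total")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return float(stat), int(df), float(p)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df_satterthwaite: float
    p_satterthwaite: float
    p_cochran_cox: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def cochran_cox_ttest(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Unequal-variance two-sample t-test, Cochran–Cox approximation primary.

    The statistic is t = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y).
    Cochran–Cox assesses it against the weighted critical value
    t* = (w_x t_{a, n_x-1} + w_y t_{a, n_y-1}) / (w_x + w_y) with
    w_i = s_i^2 / n_i; the reported Cochran–Cox p is the level at which
    |t| equals t*.  The Welch–Satterthwaite df and p are reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateModelError("need at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    wx, wy = vx / x.size, vy / y.size
    se = math.sqrt(wx + wy)
    if se == 0.0:
        raise DegenerateModelError("zero combined variance")
    t = (x.mean() - y.mean()) / se
    df_ws = (wx + wy) ** 2 / (wx**2 / (x.size - 1) + wy**2 / (y.size - 1))
    p_ws = 2.0 * stats.t.sf(abs(t), df_ws)

    def crit(alpha):
        ta = stats.t.isf(alpha / 2.0, x.size - 1)
        tb = stats.t.isf(alpha / 2.0, y.size - 1)
        return (wx * ta + wy * tb) / (wx + wy)

    at = abs(t)
    if at <= crit(1.0 - 1e-12):
        p_cc = 1.0
    elif at >= crit(1e-12):
        p_cc = 0.0
    else:
        p_cc = float(optimize.brentq(lambda a: crit(a) - at, 1e-12, 1.0 - 1e-12,
                                     xtol=1e-12))
    return TTestResult(t=float(t), df_satterthwaite=float(df_ws),
                       p_satterthwaite=float(p_ws), p_cochran_cox=p_cc,
                       mean_x=float(x.mean()), mean_y=float(y.mean()),
                       n_x=int(x.size), n_y=int(y.size))


#: Categorical features and the binnings used in subgroup comparisons.
CATEGORICAL_BINNINGS = {
    "sex": None,
    "race": None,
    "marital_status": None,
    "education": None,
    "employment": None,
    "income_monthly_usd": [(-math.inf, 2000.0), (2000.0, 4000.0), (4000.0, math.inf)],
    "mde_length_months": [(-math.inf, 6.0), (6.0, 24.0), (24.0, math.inf)],
    "n_lifetime_mdes": [(-math.inf, 3.0), (3.0, 6.0), (6.0, math.inf)],
    "n_comorbidities": [(-math.inf, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, math.inf)],
}
CONTINUOUS_FEATURES = ("age", "hamd17_baseline", "qids_sr", "shaps")


@dataclass
class GroupComparison:
    feature: str
    kind: str                      # "categorical" | "continuous"
    table: Optional[pd.DataFrame] = None
    chi2: Optional[float] = None
    df: Optional[int] = None
    ttest: Optional[TTestResult] = None
    p: float = float("nan")
    notes: str = ""
    extras: dict = field(default_factory=dict)


def _bin_numeric(values: pd.Series, edges) -> pd.Series:
    def lab(v):
        for lo, hi in edges:
            if lo < v <= hi:
                return f"({lo},{hi}]"
        return np.nan
    return values.map(lab)


def compare_groups(demographics: pd.DataFrame, labels: Sequence[str],
                   features: Optional[Sequence[str]] = None) -> list[GroupComparison]:
    """Subgroup comparison report: engaged vs disengaged on baseline features.

    Categorical features get a contingency table and uncorrected Pearson
    chi-square; continuous scales get the Cochran–Cox t-test.  Missing
    values are dropped per feature (pairwise deletion).
    """
    demo = demographics.reset_index(drop=True).copy()
    demo["_label"] = list(labels)
    if features is None:
        features = [f for f in list(CATEGORICAL_BINNINGS) + list(CONTINUOUS_FEATURES)
                    if f in demo.columns]
    out: list[GroupComparison] = []
    for feat in features:
        if feat not in demo.columns:
            raise KeyError(f"unknown feature {feat!r}")
        col = demo[feat]
        if feat in CONTINUOUS_FEATURES:
            sub = demo[["_label", feat]].dropna()
            res = cochran_cox_ttest(
                sub.loc[sub["_label"] == DISENGAGED, feat],
                sub.loc[sub["_label"] == ENGAGED, feat])
            out.append(GroupComparison(feature=feat, kind="continuous",
                                       ttest=res, p=res.p_cochran_cox))
            continue
        edges = CATEGORICAL_BINNINGS.get(feat)
        binned = _bin_numeric(col, edges) if edges is not None else col
        sub = pd.DataFrame({"_label": demo["_label"], "cat": binned}).dropna()
        tab = pd.crosstab(sub["cat"], sub["_label"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            raise DegenerateTableError(
                f"feature {feat!r}: fewer than 2 categories or 2 labels observed")
        chi2, df, p = chisq_independence(tab.to_numpy())
        out.append(GroupComparison(feature=feat, kind="categorical",
                                   table=tab, chi2=chi2, df=df, p=p))
    return out


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten a comparison report into a delimited-text-friendly table."""
    rows = []
    for c in comparisons:
        if c.kind == "categorical":
            rows.append({"feature": c.feature, "test": "chi2",
                         "statistic": c.chi2, "df": c.df, "p": c.p})
        else:
            rows.append({"feature": c.feature, "test": "cochran_cox_t",
                         "statistic": c.ttest.t, "df": c.ttest.df_satterthwaite,
                         "p": c.p})
    return pd.DataFrame(rows, columns=["feature", "test", "statistic", "df", "p"])
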