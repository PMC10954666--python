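"""Time-to-event and two-sample inference machinery.

Product-limit (Kaplan-Meier) estimation with a step-curve container, median
follow-up by the reverse Kaplan-Meier method, the two-group log-rank test,
univariable Cox proportional-hazards fits (Breslow tie handling by default,
Efron switchable), odds / odds-ratio estimates with Wald intervals, the
Shapiro-Wilk-gated two-sample location test, and Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "KMCurve", "EffectEstimate", "km_estimate", "km_median_iqr",
    "reverse_km_followup", "logrank_test", "cox_hr", "logistic_odds",
    "logistic_or", "compare_continuous", "fisher_exact",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class EffectEstimate:
    kind: str  # odds | odds_ratio | hazard_ratio
    point: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int


@dataclass
class KMCurve:
    """Right-continuous product-limit step curve; S(0) = 1."""

    event_times: np.ndarray   # distinct times with >= 1 event
    survival: np.ndarray      # S at each event time (after the drop)
    at_risk: np.ndarray       # risk-set size just before each event time
    censor_marks: np.ndarray  # distinct times with >= 1 censoring
    n: int
    max_time: float           # largest observed (event or censor) time
    greenwood: np.ndarray | None = None  # cumulative d / (n (n - d))

    def survival_at(self, t) -> np.ndarray:
        """Step lookup; carried forward flat beyond the last event time."""
        t = np.asarray(t, float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def median(self) -> float:
        return _crossing_time(self.event_times, self.survival, 0.5)


def _crossing_time(times: np.ndarray, surv: np.ndarray, level: float) -> float:
    """First time with S(t) <= level; NaN if the curve never crosses."""
    below = surv <= level + 1e-12
    return float(times[below][0]) if below.any() else float("nan")


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator; at tied times events precede censorings."""
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    if t.size == 0 or t.size != e.size:
        raise ValueError("times and events must be equal-length and non-empty")
    if (t < 0).any():
        raise ValueError("negative times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n_at_risk = t.size - np.searchsorted(t, uniq, side="left")
    d = np.array([(e[t == u] == 1).sum() for u in uniq], float)
    c = np.array([(e[t == u] == 0).sum() for u in uniq], float)
    has_event = d > 0
    surv_steps = 1.0 - d[has_event] / n_at_risk[has_event]
    surv = np.cumprod(surv_steps)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d[has_event] / (n_at_risk[has_event] * (n_at_risk[has_event] - d[has_event]))
    gw_terms = np.where(np.isfinite(gw_terms), gw_terms, np.inf)
    return KMCurve(
        event_times=uniq[has_event],
        survival=surv,
        at_risk=n_at_risk[has_event].astype(int),
        censor_marks=uniq[c > 0],
        n=int(t.size),
        max_time=float(t.max()),
        greenwood=np.cumsum(gw_terms),
    )


def km_median_iqr(curve: KMCurve) -> tuple[float, float, float]:
    """(median, q1, q3) survival times: first crossings of 0.5, 0.75, 0.25.

    NaN marks a quantile the curve never reaches (e.g. a plateau above it).
    """
    med = _crossing_time(curve.event_times, curve.survival, 0.5)
    q1 = _crossing_time(curve.event_times, curve.survival, 0.75)
    q3 = _crossing_time(curve.event_times, curve.survival, 0.25)
    return med, q1, q3


def reverse_km_followup(times, events) -> tuple[float, float, float]:
    """Median follow-up and 95%-CI by the reverse Kaplan-Meier method:
    censorings become the events of interest.  Undefined (with a warning)
    when no observation is censored."""
    e = np.asarray(events, float)
    if (e == 0).sum() == 0:
        warnings.warn("no censored observations; median follow-up undefined")
        return float("nan"), float("nan"), float("nan")
    curve = km_estimate(times, 1.0 - e)
    med = curve.median()
    if curve.greenwood is None or curve.event_times.size == 0:
        return med, float("nan"), float("nan")
    s = curve.survival
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(curve.greenwood) / np.abs(np.log(s))
        loglog = np.log(-np.log(s))
        upper_curve = np.exp(-np.exp(loglog - Z95 * se))  # higher survival
        lower_curve = np.exp(-np.exp(loglog + Z95 * se))
    ok = np.isfinite(s) & (s > 0) & (s < 1)
    t_ok = curve.event_times[ok]
    lo = _crossing_time(t_ok, upper_curve[ok], 0.5)
    hi = _crossing_time(t_ok, lower_curve[ok], 0.5)
    return med, min(lo, hi), max(lo, hi)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], float)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if (ea == 1).sum() == 0 or (eb == 1).sum() == 0:
        warnings.warn("a group has zero events; log-rank statistic may be degenerate")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    uniq = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in uniq:
        at_risk = t >= u
        n_i = at_risk.sum()
        n_a = (at_risk & (g == 0)).sum()
        d_i = ((t == u) & (e == 1)).sum()
        d_a = ((t == u) & (e == 1) & (g == 0)).sum()
        o_minus_e += d_a - d_i * n_a / n_i
        if n_i > 1:
            var += d_i * (n_a / n_i) * (1 - n_a / n_i) * (n_i - d_i) / (n_i - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_hr(times, events, covariate, name: str = "covariate",
           ties: str = "breslow") -> EffectEstimate:
    """Univariable Cox proportional-hazards fit (partial likelihood).

    Breslow tie handling by default (``ties="efron"`` to switch); Wald CI
    and p-value.  A constant covariate or non-convergence raises a named
    error; near-separation (exploding standard error) is flagged.
    """
    df = pd.DataFrame({"t": np.asarray(times, float),
                       "e": np.asarray(events, float),
                       "x": np.asarray(covariate, float)}).dropna()
    if df["e"].sum() < 1:
        raise ValueError(f"{name}: no events")
    if df["x"].nunique() < 2:
        raise ValueError(f"{name}: constant covariate")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.PHReg(df["t"], df[["x"]], status=df["e"], ties=ties)
            res = model.fit()
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"{name}: Cox fit failed ({exc})") from exc
    coef = float(res.params[0])
    se = float(res.bse[0])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
        warnings.warn(f"{name}: possible complete separation in Cox fit")
    p = float(2 * stats.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    return EffectEstimate("hazard_ratio", float(np.exp(coef)),
                          float(np.exp(coef - Z95 * se)),
                          float(np.exp(coef + Z95 * se)), p, len(df))


def logistic_odds(successes: int, failures: int) -> EffectEstimate:
    """Odds of success with Wald 95%-CI: exp(log(s/f) +/- 1.96 sqrt(1/s + 1/f))."""
    if successes < 0 or failures < 0 or successes + failures < 1:
        raise ValueError("need non-negative counts with at least one trial")
    if successes == 0 or failures == 0:
        warnings.warn("zero cell; odds CI undefined")
        odds = np.inf if failures == 0 else 0.0
        return EffectEstimate("odds", odds, float("nan"), float("nan"),
                              float("nan"), successes + failures)
    odds = successes / failures
    se = np.sqrt(1.0 / successes + 1.0 / failures)
    p = float(2 * stats.norm.sf(abs(np.log(odds)) / se))
    return EffectEstimate("odds", float(odds),
                          float(odds * np.exp(-Z95 * se)),
                          float(odds * np.exp(Z95 * se)), p,
                          successes + failures)


def logistic_or(outcome, covariate, haldane: bool = False) -> EffectEstimate:
    """Odds ratio for a binary outcome.

    Binary covariate: 2x2 cross-product with Wald CI on the log scale
    (optionally Haldane-corrected on zero cells).  Continuous covariate:
    univariable logistic regression, OR per unit.
    """
    df = pd.DataFrame({"y": np.asarray(outcome, float),
                       "x": np.asarray(covariate, float)}).dropna()
    xs = df["x"].unique()
    if set(np.unique(xs)).issubset({0.0, 1.0}) and len(xs) == 2:
        n11 = ((df.y == 1) & (df.x == 1)).sum()
        n01 = ((df.y == 0) & (df.x == 1)).sum()
        n10 = ((df.y == 1) & (df.x == 0)).sum()
        n00 = ((df.y == 0) & (df.x == 0)).sum()
        cells = np.array([n11, n01, n10, n00], float)
        if (cells == 0).any():
            if not haldane:
                warnings.warn("zero cell; odds-ratio CI undefined (set haldane=True)")
                point = float("inf") if (n01 == 0 or n10 == 0) and n11 * n00 > 0 else 0.0
                return EffectEstimate("odds_ratio", point, float("nan"),
                                      float("nan"), float("nan"), len(df))
            cells = cells + 0.5
        n11, n01, n10, n00 = cells
        or_ = (n11 * n00) / (n01 * n10)
        se = np.sqrt(np.sum(1.0 / cells))
        p = float(2 * stats.norm.sf(abs(np.log(or_)) / se))
        return EffectEstimate("odds_ratio", float(or_),
                              float(or_ * np.exp(-Z95 * se)),
                              float(or_ * np.exp(Z95 * se)), p, len(df))
    if df["x"].nunique() < 2:
        raise ValueError("constant covariate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(df["y"], sm.add_constant(df[["x"]])).fit(disp=False)
    coef, se = float(res.params["x"]), float(res.bse["x"])
    p = float(2 * stats.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    return EffectEstimate("odds_ratio", float(np.exp(coef)),
                          float(np.exp(coef - Z95 * se)),
                          float(np.exp(coef + Z95 * se)), p, len(df))


def compare_continuous(a, b, alpha: float = 0.05, seed: int = 0,
                       shapiro_cap: int = 5000) -> tuple[str, float, float]:
    """Shapiro-Wilk-gated two-sample test.

    Both samples normal at the gate's alpha -> two-sided unpaired t-test;
    otherwise the two-sided Wilcoxon rank-sum (Mann-Whitney) test with the
    tie-corrected normal approximation and continuity correction.
    Returns (test_name, statistic, p).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs >= 3 non-missing values")
    rng = np.random.default_rng(seed)

    def _shapiro_p(x):
        if np.ptp(x) == 0:
            return 0.0  # degenerate: clearly non-normal
        if x.size > shapiro_cap:
            x = rng.choice(x, shapiro_cap, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue

    if _shapiro_p(a) > alpha and _shapiro_p(b) > alpha:
        res = stats.ttest_ind(a, b)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return "wilcoxon-rank-sum", float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p (probability-mass summation convention).

    A zero row or column margin carries no information: p = 1 with a warning.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        warnings.warn("zero margin; Fisher p = 1")
        return 1.0
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])
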