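"""Normalized fidelity scores between an original and a synthetic cohort.

Three scores, each scaled to [0, 1] with 1 meaning an exact distributional
copy: Regularized Support Coverage (per-category coverage with Laplace
smoothing), the Basic Statistical Measure (agreement of mean / median / SD
of min-max-normalized continuous variables), and the Log-Transformed
Correlation Score (agreement of the mixed-type association matrices, with
continuous variables log1p-transformed before correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (CATEGORICAL_KINDS, MISSING, NUMERIC_KINDS, BinnedCohort,
                     CohortTable, bin_numeric)

__all__ = [
    "FidelityReport", "regularized_support_coverage",
    "basic_statistical_measure", "association_matrix",
    "log_transformed_correlation_score", "fidelity_report",
    "rsc_for_variable", "bsm_for_values",
]


@dataclass
class FidelityReport:
    rsc: float
    bsm: float
    ltcs: float
    rsc_per_variable: dict = field(default_factory=dict)
    bsm_per_variable: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"rsc": self.rsc, "bsm": self.bsm, "ltcs": self.ltcs,
                "rsc_per_variable": self.rsc_per_variable,
                "bsm_per_variable": self.bsm_per_variable}


def _category_labels(cohort: CohortTable, name: str) -> pd.Series:
    v = cohort.schema[name]
    col = cohort.df[name]
    if v.kind in ("binary", "event_indicator"):
        lab = col.map(lambda x: MISSING if pd.isna(x) else f"{int(x)}")
    else:
        lab = col.map(lambda x: MISSING if pd.isna(x) else str(x))
    return lab


def _rsc_from_counts(real_counts: np.ndarray, syn_counts: np.ndarray) -> float:
    """Mean over categories of min(1, p_syn / p_real), Laplace-smoothed."""
    k = len(real_counts)
    pr = (real_counts + 1.0) / (real_counts.sum() + k)
    ps = (syn_counts + 1.0) / (syn_counts.sum() + k)
    return float(np.clip(np.mean(np.minimum(1.0, ps / pr)), 0.0, 1.0))


def rsc_for_variable(real: CohortTable, syn: CohortTable, name: str) -> float:
    v = real.schema[name]
    if v.kind in NUMERIC_KINDS:
        br = bin_numeric(real, edges_from=real)
        bs = bin_numeric(syn, edges_from=real)
        cats = list(br.categories(name))
        rc = np.array([(br.df[name] == c).sum() for c in cats], float)
        sc = np.array([(bs.df[name] == c).sum() for c in cats], float)
    else:
        cats = list(v.value_categories) + ([MISSING] if v.missing_allowed else [])
        lr, ls = _category_labels(real, name), _category_labels(syn, name)
        rc = np.array([(lr == c).sum() for c in cats], float)
        sc = np.array([(ls == c).sum() for c in cats], float)
    return _rsc_from_counts(rc, sc)


def regularized_support_coverage(real: CohortTable, syn: CohortTable,
                                 include_continuous: bool = True,
                                 variables=None) -> tuple[float, dict]:
    """Per-variable support coverage, averaged; continuous variables enter
    through their 10-bin decile quantization on the real cohort's edges
    (switchable off to score categorical variables only)."""
    if real.schema.names != syn.schema.names:
        raise ValueError("schema mismatch between cohorts")
    names = variables or [
        v.name for v in real.schema.variables
        if include_continuous or v.kind in CATEGORICAL_KINDS
    ]
    br = bs = None
    if any(real.schema[nm].kind in NUMERIC_KINDS for nm in names):
        br = bin_numeric(real, edges_from=real)
        bs = bin_numeric(syn, edges_from=real)
    per: dict[str, float] = {}
    for nm in names:
        v = real.schema[nm]
        if v.kind in NUMERIC_KINDS:
            cats = list(br.categories(nm))
            rc = np.array([(br.df[nm] == c).sum() for c in cats], float)
            sc = np.array([(bs.df[nm] == c).sum() for c in cats], float)
        else:
            cats = list(v.value_categories) + ([MISSING] if v.missing_allowed else [])
            lr, ls = _category_labels(real, nm), _category_labels(syn, nm)
            rc = np.array([(lr == c).sum() for c in cats], float)
            sc = np.array([(ls == c).sum() for c in cats], float)
        per[nm] = _rsc_from_counts(rc, sc)
    overall = float(np.clip(np.mean(list(per.values())), 0.0, 1.0))
    return overall, per


def bsm_for_values(real_vals: np.ndarray, syn_vals: np.ndarray) -> float:
    """BSM for one variable: mean/median/SD agreement after normalizing both
    samples by the real sample's min-max."""
    r = np.asarray(real_vals, float)
    s = np.asarray(syn_vals, float)
    r, s = r[np.isfinite(r)], s[np.isfinite(s)]
    if r.size < 2 or s.size < 2:
        raise ValueError("need >= 2 non-missing values in both cohorts")
    lo, hi = r.min(), r.max()
    span = hi - lo
    if span == 0:
        span = 1.0
    rn, sn = (r - lo) / span, (s - lo) / span
    scores = [
        np.clip(1.0 - abs(rn.mean() - sn.mean()), 0.0, 1.0),
        np.clip(1.0 - abs(np.median(rn) - np.median(sn)), 0.0, 1.0),
        np.clip(1.0 - abs(rn.std(ddof=1) - sn.std(ddof=1)), 0.0, 1.0),
    ]
    return float(np.mean(scores))


def basic_statistical_measure(real: CohortTable, syn: CohortTable,
                              variables=None) -> tuple[float, dict]:
    if real.schema.names != syn.schema.names:
        raise ValueError("schema mismatch between cohorts")
    names = variables or list(real.schema.numeric_names)
    per: dict[str, float] = {}
    for nm in names:
        try:
            per[nm] = bsm_for_values(real.nonmissing(nm), syn.nonmissing(nm))
        except ValueError:
            warnings.warn(f"{nm}: fewer than 2 non-missing values, excluded")
    if not per:
        raise ValueError("no scorable continuous variables")
    return float(np.clip(np.mean(list(per.values())), 0.0, 1.0)), per


# ---------------------------------------------------------------------------
# Mixed-type association matrix and the correlation score

def _cramers_v(x: pd.Series, y: pd.Series) -> float:
    tab = pd.crosstab(x, y)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if n and k else 0.0


def _correlation_ratio(values: np.ndarray, groups: pd.Series) -> float:
    """eta: sqrt of between-group sum of squares over total."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    if df["g"].nunique() < 2 or len(df) < 3:
        return 0.0
    grand = df["v"].mean()
    ssb = df.groupby("g")["v"].agg(["mean", "size"]).eval("size * (mean - @grand) ** 2").sum()
    sst = ((df["v"] - grand) ** 2).sum()
    return float(np.sqrt(ssb / sst)) if sst > 0 else 0.0


def _log1p_safe(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    return np.log1p(np.clip(v, -1.0 + 1e-12, None))


def association_matrix(cohort: CohortTable, variables=None) -> pd.DataFrame:
    """Symmetric [0,1] association matrix: |Pearson r| on log1p values for
    continuous pairs, Cramer's V for categorical pairs, the correlation
    ratio for mixed pairs.  Pairwise-complete on non-missing values; entries
    with fewer than 3 complete pairs are NaN (undefined)."""
    names = list(variables or cohort.schema.names)
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    numeric = set(cohort.schema.numeric_names)
    flat = CohortTable(cohort.schema, cohort.df.reset_index(drop=True), cohort.label)
    cols: dict[str, pd.Series] = {}
    for nm in names:
        if nm in numeric:
            raw = flat.df[nm]
            cols[nm] = pd.Series(_log1p_safe(raw.to_numpy(float))).where(raw.notna())
        else:
            cols[nm] = _category_labels(flat, nm).replace(MISSING, np.nan)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            xa, xb = cols[a], cols[b]
            ok = xa.notna() & xb.notna()
            if ok.sum() < 3:
                val = np.nan
            elif a in numeric and b in numeric:
                va, vb = xa[ok].astype(float), xb[ok].astype(float)
                if va.std() == 0 or vb.std() == 0:
                    val = 0.0
                else:
                    val = abs(float(np.corrcoef(va, vb)[0, 1]))
            elif a not in numeric and b not in numeric:
                val = _cramers_v(xa[ok], xb[ok])
            else:
                num, cat = (a, b) if a in numeric else (b, a)
                val = _correlation_ratio(cols[num][ok].to_numpy(float), cols[cat][ok])
            out.loc[a, b] = out.loc[b, a] = val
    return out


def log_transformed_correlation_score(real: CohortTable, syn: CohortTable,
                                      variables=None) -> float:
    """1 minus the mean absolute difference of the two association matrices
    over defined off-diagonal pairs, clipped to [0, 1]."""
    if real.schema.names != syn.schema.names:
        raise ValueError("schema mismatch between cohorts")
    ar = association_matrix(real, variables).to_numpy()
    as_ = association_matrix(syn, variables).to_numpy()
    mask = ~np.eye(ar.shape[0], dtype=bool) & np.isfinite(ar) & np.isfinite(as_)
    if not mask.any():
        raise ValueError("all variable pairs undefined")
    return float(np.clip(1.0 - np.mean(np.abs(ar[mask] - as_[mask])), 0.0, 1.0))


def fidelity_report(real: CohortTable, syn: CohortTable) -> FidelityReport:
    rsc, rsc_per = regularized_support_coverage(real, syn)
    bsm, bsm_per = basic_statistical_measure(real, syn)
    ltcs = log_transformed_correlation_score(real, syn)
    return FidelityReport(rsc=rsc, bsm=bsm, ltcs=ltcs,
                          rsc_per_variable=rsc_per, bsm_per_variable=bsm_per)
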