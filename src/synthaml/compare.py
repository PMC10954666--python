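"""Result-style comparisons between an original cohort and synthetic cohorts.

Baseline-characteristic tables (two-sample tests per variable), outcome
tables (CR odds, KM medians, between-cohort hazard ratios, log-rank tests),
alteration-frequency tables, relative co-occurrence difference matrices, and
the univariable risk-marker concordance analysis asking whether every
marker-endpoint effect keeps its direction and significance in the
synthetic cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CATEGORICAL_KINDS, NUMERIC_KINDS, CohortTable
from .survival import (cox_hr, compare_continuous, fisher_exact, km_estimate,
                       km_median_iqr, logistic_odds, logistic_or, logrank_test)

__all__ = [
    "ALPHA", "RISK_MARKER_PANEL", "baseline_table", "outcome_table",
    "alteration_frequencies", "cooccurrence_diff", "univariable_panel",
    "concordance_matrix", "classify_concordance",
]

ALPHA = 0.05  # two-sided significance threshold used throughout

#: established favorable / intermediate / adverse risk markers plus age
RISK_MARKER_PANEL = (
    "normal_karyotype", "t_8_21", "inv_16", "NPM1", "CEBPA_bZIP",
    "FLT3_ITD", "t_9_11",
    "complex_karyotype", "minus_5", "del_5q", "minus_7", "minus_17",
    "TP53", "RUNX1", "ASXL1",
    "age",
)


def _fmt_cont(cohort: CohortTable, name: str) -> str:
    v = cohort.nonmissing(name).astype(float)
    if v.size == 0:
        return "-"
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _level_counts(cohort: CohortTable, name: str, level: str) -> tuple[int, int]:
    """(count at level, non-missing count)."""
    v = cohort.schema[name]
    col = cohort.df[name].dropna()
    if v.kind in ("binary", "event_indicator"):
        col = col.map(lambda x: f"{int(x)}")
    else:
        col = col.astype(str)
    return int((col == level).sum()), int(len(col))


def _bh_adjust(df: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini-Hochberg column; the raw p and its flag stay."""
    from statsmodels.stats.multitest import multipletests

    ok = df["p"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["p_bh"] = adj
    df["significant_bh"] = df["p_bh"] < ALPHA
    return df


def baseline_table(original: CohortTable, synthetics: dict | list,
                   variables=None, adjust: bool = False) -> pd.DataFrame:
    """Two-sample comparison of each variable against the original cohort.

    Continuous variables use the Shapiro-gated t / Wilcoxon test; binary and
    categorical variables use per-level Fisher's exact tests (level vs rest
    on non-missing counts).  Percentages are reported over total n with the
    missing count alongside.  ``adjust=True`` appends Benjamini-Hochberg
    columns; the unadjusted per-test flags always remain.
    """
    synthetics = _as_dict(synthetics)
    names = variables or [v.name for v in original.schema.variables
                          if v.kind in NUMERIC_KINDS + ("binary", "categorical")]
    rows = []
    for nm in names:
        v = original.schema[nm]
        if v.kind in NUMERIC_KINDS:
            for lab, syn in synthetics.items():
                test, statv, p = compare_continuous(
                    original.nonmissing(nm), syn.nonmissing(nm))
                rows.append({"variable": nm, "level": "", "cohort": lab,
                             "original_summary": _fmt_cont(original, nm),
                             "cohort_summary": _fmt_cont(syn, nm),
                             "test_used": test, "p": p,
                             "significant": p < ALPHA})
        else:
            for level in v.value_categories:
                c_o, n_o = _level_counts(original, nm, level)
                for lab, syn in synthetics.items():
                    c_s, n_s = _level_counts(syn, nm, level)
                    p = fisher_exact([[c_o, n_o - c_o], [c_s, n_s - c_s]])
                    rows.append({
                        "variable": nm, "level": level, "cohort": lab,
                        "original_summary": f"{c_o} ({100 * c_o / original.n:.1f})",
                        "cohort_summary": f"{c_s} ({100 * c_s / syn.n:.1f})",
                        "test_used": "fisher-exact", "p": p,
                        "significant": p < ALPHA})
    out = pd.DataFrame(rows)
    return _bh_adjust(out) if adjust and len(out) else out


def _as_dict(synthetics) -> dict:
    if isinstance(synthetics, dict):
        return synthetics
    return {getattr(s, "label", f"synthetic_{i}"): s for i, s in enumerate(synthetics)}


def outcome_table(original: CohortTable, synthetics: dict | list) -> pd.DataFrame:
    """Outcome comparison: CR rate and odds, KM median (IQR) for EFS and OS,
    and per synthetic cohort the Fisher p for CR plus the between-cohort
    hazard ratio (Cox on the pooled data with a cohort indicator) and
    log-rank p for each survival endpoint."""
    synthetics = _as_dict(synthetics)
    cr_name = original.schema.endpoint("cr")
    rows = []
    for lab, cohort in {"original": original, **synthetics}.items():
        cr = cohort.df[cr_name].dropna()
        succ, fail = int((cr == 1).sum()), int((cr == 0).sum())
        odds = logistic_odds(succ, fail)
        row = {"cohort": lab, "cr_n": succ,
               "cr_percent": 100 * succ / cohort.n,
               "cr_odds": odds.point, "cr_odds_ci_low": odds.ci_low,
               "cr_odds_ci_high": odds.ci_high}
        for ep in ("efs", "os"):
            t, e = cohort.survival(ep)
            med, q1, q3 = km_median_iqr(km_estimate(t, e))
            row[f"{ep}_median"] = med
            row[f"{ep}_q1"], row[f"{ep}_q3"] = q1, q3
        if lab != "original":
            co = original.df[cr_name].dropna()
            row["cr_fisher_p"] = fisher_exact(
                [[int((co == 1).sum()), int((co == 0).sum())], [succ, fail]])
            for ep in ("efs", "os"):
                to, eo = original.survival(ep)
                ts, es = cohort.survival(ep)
                hr = cox_hr(np.concatenate([to, ts]), np.concatenate([eo, es]),
                            np.concatenate([np.zeros(to.size), np.ones(ts.size)]),
                            name=f"{lab}:{ep}")
                _, p_lr = logrank_test((to, eo), (ts, es))
                row[f"{ep}_hr"] = hr.point
                row[f"{ep}_hr_ci_low"], row[f"{ep}_hr_ci_high"] = hr.ci_low, hr.ci_high
                row[f"{ep}_logrank_p"] = p_lr
        rows.append(row)
    return pd.DataFrame(rows)


def alteration_frequencies(original: CohortTable, synthetics: dict | list,
                           alterations=None,
                           highlight_p: float = 0.001) -> pd.DataFrame:
    """Per-alteration percentages and synthetic-vs-original Fisher p-values;
    differences below ``highlight_p`` are flagged as highly significant."""
    synthetics = _as_dict(synthetics)
    names = alterations or list(original.schema.binary_names)
    rows = []
    for nm in names:
        c_o, n_o = _level_counts(original, nm, "1")
        row = {"alteration": nm, "original_count": c_o,
               "original_percent": 100 * c_o / original.n}
        for lab, syn in synthetics.items():
            c_s, n_s = _level_counts(syn, nm, "1")
            p = fisher_exact([[c_o, n_o - c_o], [c_s, n_s - c_s]])
            row[f"{lab}_count"] = c_s
            row[f"{lab}_percent"] = 100 * c_s / syn.n
            row[f"{lab}_p"] = p
            row[f"{lab}_highly_significant"] = p < highlight_p
        rows.append(row)
    return pd.DataFrame(rows)


def cooccurrence_diff(original: CohortTable, syn: CohortTable,
                      alterations=None) -> pd.DataFrame:
    """Relative co-occurrence difference matrix in percent, clamped to
    [-100, 100]: off-diagonal entries compare the proportion of patients
    carrying both alterations; the diagonal compares marginal frequencies.
    The reference floor epsilon = 1/n_original keeps rare pairs finite."""
    names = list(alterations or original.schema.binary_names)
    if len(names) < 2:
        raise ValueError("need >= 2 binary variables")
    eps = 1.0 / original.n

    def pair_props(cohort: CohortTable) -> np.ndarray:
        x = (cohort.df[names] == 1).to_numpy(float)
        return (x.T @ x) / cohort.n

    po, ps = pair_props(original), pair_props(syn)
    rel = 100.0 * (ps - po) / np.maximum(po, eps)
    rel = np.clip(rel, -100.0, 100.0)
    return pd.DataFrame(rel, index=names, columns=names)


def univariable_panel(cohort: CohortTable, markers=RISK_MARKER_PANEL,
                      endpoints=("cr", "efs", "os")) -> pd.DataFrame:
    """Univariable effect per (marker, endpoint): logistic OR for CR, Cox HR
    for the survival endpoints, with Wald CI and p.  Markers with fewer than
    5 carriers are reported with a wide-CI warning flag."""
    rows = []
    for marker in markers:
        if marker not in cohort.schema:
            raise KeyError(f"marker {marker!r} not in cohort schema")
        x = cohort.df[marker].to_numpy(float)
        binary = cohort.schema[marker].kind == "binary"
        few = binary and np.nansum(x == 1) < 5
        if few:
            warnings.warn(f"{marker}: fewer than 5 carriers; CI will be wide")
        for ep in endpoints:
            if ep == "cr":
                y = cohort.df[cohort.schema.endpoint("cr")].to_numpy(float)
                est = logistic_or(y, x, haldane=True)
            else:
                t, e = cohort.survival(ep, dropna=False)
                est = cox_hr(t, e, x, name=marker)
            rows.append({"marker": marker, "endpoint": ep.upper(),
                         "kind": est.kind, "estimate": est.point,
                         "ci_low": est.ci_low, "ci_high": est.ci_high,
                         "p": est.p, "n_used": est.n_used,
                         "few_carriers": bool(few)})
    return pd.DataFrame(rows)


def classify_concordance(direction_real: int, direction_syn: int,
                         sig_real: bool, sig_syn: bool) -> str:
    """Pure classification of one marker-endpoint pair.

    inverse: opposite directions with at least one significant effect;
    concordant_significant: same direction, both significant;
    significance_discordant: same direction, exactly one significant;
    concordant_nonsignificant: everything else (no significant evidence
    of disagreement).
    """
    opposite = direction_real * direction_syn < 0
    if opposite and (sig_real or sig_syn):
        return "inverse"
    if not (sig_real or sig_syn):
        return "concordant_nonsignificant"
    if sig_real and sig_syn and not opposite:
        return "concordant_significant"
    if opposite:  # both significant, opposite direction -> already handled
        return "inverse"
    return "significance_discordant"


@dataclass
class ConcordanceSummary:
    cells: pd.DataFrame
    counts: dict
    inverse_count: int


def concordance_matrix(panel_real: pd.DataFrame,
                       panel_syn: pd.DataFrame) -> ConcordanceSummary:
    """Classify every (marker, endpoint) effect pair across two panels."""
    key = ["marker", "endpoint"]
    merged = panel_real.merge(panel_syn, on=key, suffixes=("_real", "_syn"))
    if len(merged) != len(panel_real) or len(merged) != len(panel_syn):
        raise ValueError("panels do not share identical (marker, endpoint) keys")
    cells = []
    for _, r in merged.iterrows():
        d_r = int(np.sign(np.log(r["estimate_real"]))) if r["estimate_real"] > 0 else 0
        d_s = int(np.sign(np.log(r["estimate_syn"]))) if r["estimate_syn"] > 0 else 0
        s_r, s_s = bool(r["p_real"] < ALPHA), bool(r["p_syn"] < ALPHA)
        cells.append({"marker": r["marker"], "endpoint": r["endpoint"],
                      "direction_real": d_r, "direction_syn": d_s,
                      "sig_real": s_r, "sig_syn": s_s,
                      "class": classify_concordance(d_r, d_s, s_r, s_s)})
    df = pd.DataFrame(cells)
    counts = df["class"].value_counts().to_dict()
    return ConcordanceSummary(cells=df, counts=counts,
                              inverse_count=int(counts.get("inverse", 0)))
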