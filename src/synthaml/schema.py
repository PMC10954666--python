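"""Variable dictionary, cohort table container, validation, I/O and binning.

A cohort is one row per patient.  Every variable is declared by a
:class:`VariableSpec` (kind, units, categories, missingness); the
:class:`Schema` also names the clinical endpoints: a binary complete-remission
indicator (CR) and two paired time-to-event endpoints, event-free survival
(EFS) and overall survival (OS), with EFS <= OS by definition.

Missing values are carried as NaN in memory and as the reserved category
label ``"na"`` wherever a categorical representation is needed (binned
records, generator marginals, CSV round-trips write an empty cell).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = "na"

KINDS = ("continuous", "binary", "categorical", "event_indicator", "time")

#: kinds whose in-memory values are floats
NUMERIC_KINDS = ("continuous", "time")
#: kinds represented as category labels
CATEGORICAL_KINDS = ("binary", "categorical", "event_indicator")


class CohortValidationError(ValueError):
    """Raised when a table violates its schema; ``problems`` lists offenders."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str
    units: str = ""
    categories: tuple[str, ...] | None = None
    missing_allowed: bool = True
    pair: str | None = None  # for kind=time: its event-indicator partner

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        cats = self.categories
        if self.kind in ("binary", "event_indicator") and cats is None:
            cats = ("0", "1")
        if cats is not None:
            cats = tuple(str(c) for c in cats)
            if len(set(cats)) != len(cats):
                raise ValueError(f"duplicate categories for {self.name!r}")
            if cats.count(MISSING) and not self.missing_allowed:
                raise ValueError(f"'na' category on {self.name!r} without missing_allowed")
            object.__setattr__(self, "categories", cats)
        if self.kind == "time" and not self.pair:
            raise ValueError(f"time variable {self.name!r} has no event-indicator pair")
        if self.kind == "categorical" and self.categories is None:
            raise ValueError(f"categorical variable {self.name!r} needs categories")

    @property
    def value_categories(self) -> tuple[str, ...]:
        """Categories excluding the reserved missing label."""
        return tuple(c for c in (self.categories or ()) if c != MISSING)

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "missing_allowed": self.missing_allowed}
        if self.units:
            d["units"] = self.units
        if self.categories is not None:
            d["categories"] = list(self.categories)
        if self.pair:
            d["pair"] = self.pair
        return d


@dataclass(frozen=True)
class Schema:
    variables: tuple[VariableSpec, ...]
    endpoints: dict = field(default_factory=dict)
    # endpoints: {"cr": name, "efs": (time, event), "os": (time, event)}

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("variable names not unique")
        by_name = {v.name: v for v in self.variables}
        for v in self.variables:
            if v.kind == "time":
                if v.pair not in by_name or by_name[v.pair].kind != "event_indicator":
                    raise ValueError(f"time variable {v.name!r} unpaired")
        for key, val in self.endpoints.items():
            flat = [val] if isinstance(val, str) else list(val)
            for nm in flat:
                if nm not in by_name:
                    raise ValueError(f"declared endpoint {key}={nm!r} not in schema")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def names_of_kind(self, *kinds: str) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.kind in kinds)

    @property
    def numeric_names(self) -> tuple[str, ...]:
        return self.names_of_kind(*NUMERIC_KINDS)

    @property
    def binary_names(self) -> tuple[str, ...]:
        return self.names_of_kind("binary")

    def endpoint(self, key: str):
        return self.endpoints.get(key)

    def to_dict(self) -> dict:
        eps = {k: (v if isinstance(v, str) else list(v)) for k, v in self.endpoints.items()}
        return {"variables": [v.to_dict() for v in self.variables], "endpoints": eps}

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        vs = tuple(
            VariableSpec(
                name=e["name"],
                kind=e["kind"],
                units=e.get("units", ""),
                categories=tuple(e["categories"]) if e.get("categories") else None,
                missing_allowed=e.get("missing_allowed", True),
                pair=e.get("pair"),
            )
            for e in d["variables"]
        )
        eps = {k: (v if isinstance(v, str) else tuple(v)) for k, v in d.get("endpoints", {}).items()}
        return cls(variables=vs, endpoints=eps)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Schema":
        path = str(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(d)


@dataclass
class CohortTable:
    """A validated patient-per-row table bound to its :class:`Schema`."""

    schema: Schema
    df: pd.DataFrame
    label: str = "cohort"

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self, label: str | None = None) -> "CohortTable":
        return CohortTable(self.schema, self.df.copy(), label or self.label)

    def values(self, name: str) -> pd.Series:
        return self.df[name]

    def nonmissing(self, name: str) -> np.ndarray:
        s = self.df[name]
        return s[s.notna()].to_numpy()

    def survival(self, endpoint: str, dropna: bool = True):
        """(times, events) float arrays for endpoint 'efs' or 'os'."""
        tname, ename = self.schema.endpoint(endpoint)
        t = pd.to_numeric(self.df[tname], errors="coerce")
        e = pd.to_numeric(self.df[ename], errors="coerce")
        if dropna:
            keep = t.notna() & e.notna()
            t, e = t[keep], e[keep]
        return t.to_numpy(float), e.to_numpy(float)

    def validate(self) -> None:
        problems = validate_frame(self.schema, self.df)
        if problems:
            raise CohortValidationError(problems)


def validate_frame(schema: Schema, df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    unknown = [c for c in df.columns if c not in schema.names]
    if unknown:
        problems.append(f"unknown column(s): {unknown}")
    absent = [c for c in schema.names if c not in df.columns]
    if absent:
        problems.append(f"missing column(s): {absent}")
        return problems

    for v in schema.variables:
        col = df[v.name]
        if v.kind in NUMERIC_KINDS + ("binary", "event_indicator"):
            num = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & num.isna()
            if bad.any():
                problems.append(f"{v.name}: non-numeric values in rows {_rows(bad)}")
                continue
            if v.kind == "time":
                neg = num.notna() & (num < 0)
                if neg.any():
                    problems.append(f"{v.name}: negative time in rows {_rows(neg)}")
            if v.kind in ("binary", "event_indicator"):
                lab = num.dropna()
                bad01 = ~lab.isin([0, 1])
                if bad01.any():
                    problems.append(f"{v.name}: values outside {{0,1}} in rows {_rows(bad01)}")
        else:  # categorical
            lab = col.dropna().astype(str)
            allowed = set(v.value_categories)
            bad = ~lab.isin(allowed)
            if bad.any():
                problems.append(f"{v.name}: unknown label(s) in rows {_rows(bad)}")
        if not v.missing_allowed and col.isna().any():
            problems.append(f"{v.name}: missing values present but not allowed")

    for key in ("efs", "os"):
        pair = schema.endpoint(key)
        if pair and all(p in df.columns for p in pair):
            t = pd.to_numeric(df[pair[0]], errors="coerce")
            e = pd.to_numeric(df[pair[1]], errors="coerce")
            orphan = t.isna() & e.notna() & (e == 1)
            if orphan.any():
                problems.append(f"{pair[1]}: event without {pair[0]} time in rows {_rows(orphan)}")

    efs = schema.endpoint("efs")
    os_ = schema.endpoint("os")
    if efs and os_ and efs[0] in df.columns and os_[0] in df.columns:
        te = pd.to_numeric(df[efs[0]], errors="coerce")
        to = pd.to_numeric(df[os_[0]], errors="coerce")
        viol = te.notna() & to.notna() & (te > to + 1e-9)
        if viol.any():
            problems.append(f"EFS exceeds OS in rows {_rows(viol)}")
    return problems


def _rows(mask: pd.Series, limit: int = 10) -> list:
    idx = list(np.flatnonzero(np.asarray(mask)))
    return idx[:limit] + (["..."] if len(idx) > limit else [])


# ---------------------------------------------------------------------------
# I/O

def load_cohort(path, schema_path, label: str | None = None) -> CohortTable:
    """Read a cohort CSV with its schema sidecar and validate it.

    Empty cells are the missing state.  Columns are coerced to the dtype
    their kind implies (float for numeric kinds, string labels otherwise).
    """
    schema = Schema.load(schema_path)
    df = pd.read_csv(path, dtype=str, na_values=["", "na", "NA"])
    df = coerce_frame(schema, df)
    cohort = CohortTable(schema, df, label or str(path))
    cohort.validate()
    return cohort


def coerce_frame(schema: Schema, df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for v in schema.variables:
        if v.name not in df.columns:
            continue
        col = df[v.name]
        if v.kind in NUMERIC_KINDS + ("binary", "event_indicator"):
            out[v.name] = pd.to_numeric(col, errors="coerce").astype(float)
        else:
            out[v.name] = col.astype(object).where(col.notna(), np.nan)
    frame = pd.DataFrame(out)
    return frame[[c for c in schema.names if c in frame.columns]]


def write_cohort(cohort: CohortTable, path, schema_path=None) -> None:
    """Write cohort CSV (empty cell = missing); optionally the schema sidecar."""
    df = cohort.df.copy()
    for v in cohort.schema.variables:
        if v.kind == "time":
            df[v.name] = df[v.name].map(lambda x: "" if pd.isna(x) else f"{x:.1f}")
        elif v.kind in ("binary", "event_indicator"):
            df[v.name] = df[v.name].map(lambda x: "" if pd.isna(x) else f"{int(x)}")
    df.to_csv(path, index=False, na_rep="")
    if schema_path is not None:
        cohort.schema.save(schema_path)


# ---------------------------------------------------------------------------
# Binning (10-level quantization used by the privacy assessment)

@dataclass
class BinnedCohort:
    """All-categorical view of a cohort: numeric variables become 10 decile
    bins of a reference cohort, every missing value becomes the label "na".
    """

    schema: Schema
    df: pd.DataFrame  # string labels, no NaN
    bin_edges: dict  # variable -> np.ndarray of n_bins+1 edges

    @property
    def n(self) -> int:
        return len(self.df)

    def categories(self, name: str) -> tuple[str, ...]:
        return self.schema[name].categories or ()


def bin_labels(n_bins: int) -> list[str]:
    return [f"b{i + 1:02d}" for i in range(n_bins)]


def bin_numeric(cohort: CohortTable, n_bins: int = 10,
                edges_from: CohortTable | None = None) -> BinnedCohort:
    """Quantize numeric variables into decile bins of a reference cohort.

    Edges are the empirical quantiles (0.1, ..., 0.9) of the reference's
    non-missing values; values outside the reference range clamp to the
    first/last bin.  Categorical kinds keep their labels; NaN maps to "na".
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ref = edges_from or cohort
    out = {}
    edges_store: dict[str, np.ndarray] = {}
    new_vars = []
    for v in cohort.schema.variables:
        col = cohort.df[v.name]
        if v.kind in NUMERIC_KINDS:
            refvals = ref.nonmissing(v.name).astype(float)
            if refvals.size == 0 or np.nanmin(refvals) == np.nanmax(refvals):
                warnings.warn(f"{v.name}: constant/empty reference, single bin")
                inner = np.array([])
                cats = [bin_labels(n_bins)[0]]
                lab = np.where(col.notna(), cats[0], MISSING)
                edges = np.array([refvals.min() if refvals.size else 0.0] * 2)
            else:
                qs = np.linspace(0, 1, n_bins + 1)
                edges = np.quantile(refvals, qs)
                inner = edges[1:-1]
                cats = bin_labels(n_bins)
                idx = np.searchsorted(inner, col.to_numpy(float), side="right")
                lab = np.where(col.notna(), np.array(cats, dtype=object)[np.clip(idx, 0, n_bins - 1)], MISSING)
            out[v.name] = lab
            edges_store[v.name] = edges
            new_vars.append(VariableSpec(v.name, "categorical", v.units,
                                         tuple(cats) + (MISSING,), True))
        else:
            if v.kind in ("binary", "event_indicator"):
                lab = col.map(lambda x: MISSING if pd.isna(x) else f"{int(x)}")
            else:
                lab = col.map(lambda x: MISSING if pd.isna(x) else str(x))
            out[v.name] = lab.to_numpy(dtype=object)
            cats = tuple(v.value_categories) + (MISSING,)
            new_vars.append(VariableSpec(v.name, "categorical", v.units, cats, True))
    bschema = Schema(tuple(new_vars), endpoints=cohort.schema.endpoints)
    return BinnedCohort(bschema, pd.DataFrame(out, columns=list(cohort.schema.names)), edges_store)


# ---------------------------------------------------------------------------
# Summaries

def summarize(cohort: CohortTable) -> pd.DataFrame:
    """Per-variable summary: continuous -> median and IQR (linear-interpolation
    quartiles); categorical kinds -> per-level count and percent of total n,
    with the missing count reported separately.
    """
    rows = []
    n = cohort.n
    for v in cohort.schema.variables:
        col = cohort.df[v.name]
        n_miss = int(col.isna().sum())
        base = {"variable": v.name, "kind": v.kind, "units": v.units,
                "n": n, "n_missing": n_miss,
                "quartile_method": "linear"}
        if v.kind in NUMERIC_KINDS:
            vals = cohort.nonmissing(v.name).astype(float)
            if vals.size == 0:
                rows.append({**base, "level": "", "median": np.nan,
                             "q1": np.nan, "q3": np.nan})
            else:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
                rows.append({**base, "level": "", "median": med, "q1": q1, "q3": q3})
        else:
            levels = v.value_categories
            obs = col.dropna()
            if v.kind in ("binary", "event_indicator"):
                obs = obs.map(lambda x: f"{int(x)}")
            else:
                obs = obs.astype(str)
            for lev in levels:
                cnt = int((obs == lev).sum())
                rows.append({**base, "level": lev, "count": cnt,
                             "percent": 100.0 * cnt / n if n else np.nan})
    return pd.DataFrame(rows)
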