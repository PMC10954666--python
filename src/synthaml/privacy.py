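"""Distance-based privacy assessment of a synthetic cohort.

The synthetic cohort is compared, in a fully categorical (10-bin-quantized)
feature space, against the training portion of the original cohort and a
held-out test portion of equal size: if synthetic records sit no closer to
training records than to test records, the generator has not memorized its
training patients.  The leakage coefficient

    (syn -> test) / (syn -> train) - 1

on average minimum Hamming distances is flagged above 0.05.  Exact-match
counting on the raw (un-binned) records complements the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import MISSING, BinnedCohort, CohortTable, bin_numeric

__all__ = [
    "PrivacyReport", "hamming_distance", "partition_training",
    "avg_min_distance", "min_distances", "leakage_coefficient",
    "privacy_leakage_coefficient", "count_exact_matches",
    "bin_numeric_for_privacy",
]

LEAKAGE_THRESHOLD = 0.05


def bin_numeric_for_privacy(cohort: CohortTable, original: CohortTable,
                            n_bins: int = 10) -> BinnedCohort:
    """Quantize with edges always taken from the original cohort, so
    synthetic and original records share one categorical label space."""
    return bin_numeric(cohort, n_bins=n_bins, edges_from=original)


@dataclass
class PrivacyReport:
    avg_min_dist_syn_train: float
    avg_min_dist_syn_test: float
    median_dist_train: float
    median_dist_test: float
    leakage_coefficient: float
    threshold: float
    breach_flag: bool
    exact_matches: int | None = None
    baseline_avg_min_train: float | None = None
    baseline_avg_min_test: float | None = None
    k_subsets: int = 0
    partition_seed: int | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _label_matrix(binned: BinnedCohort) -> np.ndarray:
    return binned.df.astype(str).to_numpy(dtype=object)


def hamming_distance(a, b) -> int:
    """Number of differing positions between two categorical records;
    the missing label "na" equals itself."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("records have different lengths")
    return int(np.sum(a != b))


def _codes(query: BinnedCohort, reference: BinnedCohort) -> tuple[np.ndarray, np.ndarray]:
    if tuple(query.df.columns) != tuple(reference.df.columns):
        raise ValueError("schema mismatch between binned cohorts")
    qs, rs = [], []
    for col in query.df.columns:
        cats = pd.unique(np.concatenate([query.df[col].astype(str).to_numpy(),
                                         reference.df[col].astype(str).to_numpy()]))
        mapping = {c: i for i, c in enumerate(cats)}
        qs.append(query.df[col].astype(str).map(mapping).to_numpy())
        rs.append(reference.df[col].astype(str).map(mapping).to_numpy())
    return np.asarray(qs).T.astype(np.int32), np.asarray(rs).T.astype(np.int32)


def min_distances(query: BinnedCohort, reference: BinnedCohort,
                  exclude_self: bool | None = None,
                  chunk: int = 256) -> np.ndarray:
    """Per-query-record minimum Hamming distance to the reference records.

    When query and reference are the same table (or ``exclude_self=True``
    with equal sizes), the trivial self-pair on the diagonal is excluded.
    """
    if reference.n == 0:
        raise ValueError("empty reference")
    q, r = _codes(query, reference)
    if exclude_self is None:
        exclude_self = query.df is reference.df or (
            query.n == reference.n and query.df.equals(reference.df))
    out = np.empty(q.shape[0], dtype=float)
    for start in range(0, q.shape[0], chunk):
        block = q[start:start + chunk]
        dist = (block[:, None, :] != r[None, :, :]).sum(axis=2).astype(float)
        if exclude_self:
            for i in range(block.shape[0]):
                j = start + i
                if j < reference.n:
                    dist[i, j] = np.inf
        out[start:start + chunk] = dist.min(axis=1)
    return out


def avg_min_distance(query: BinnedCohort, reference: BinnedCohort,
                     exclude_self: bool | None = None) -> tuple[float, float]:
    """(mean, median) of the per-query minimum Hamming distances."""
    mins = min_distances(query, reference, exclude_self=exclude_self)
    return float(np.mean(mins)), float(np.median(mins))


def leakage_coefficient(syn_to_test: float, syn_to_train: float) -> float:
    """(syn -> test) / (syn -> train) - 1 on average minimum distances."""
    if syn_to_train == 0:
        return float("inf")
    return syn_to_test / syn_to_train - 1.0


def partition_training(train: CohortTable, test_n: int, k: int = 4,
                       seed: int = 0) -> list[CohortTable]:
    """Seeded partition of the training cohort into k disjoint subsets of
    (up to) test_n rows each, for balanced distance comparisons against an
    equally sized test set.  Surplus rows stay unassigned (logged)."""
    if k < 1 or test_n < 1:
        raise ValueError("k and test_n must be >= 1")
    size = min(int(test_n), train.n // k)
    if size < 1:
        raise ValueError(f"training cohort too small for {k} subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train.n)
    surplus = train.n - k * size
    if surplus:
        warnings.warn(f"{surplus} training rows unassigned by the {k}-way partition")
    subsets = []
    for i in range(k):
        idx = perm[i * size:(i + 1) * size]
        subsets.append(CohortTable(train.schema,
                                   train.df.iloc[idx].reset_index(drop=True),
                                   f"{train.label}/subset{i + 1}"))
    return subsets


def privacy_leakage_coefficient(syn: BinnedCohort, train_subsets: list,
                                test: BinnedCohort,
                                syn_raw: CohortTable | None = None,
                                original_raw: CohortTable | None = None,
                                threshold: float = LEAKAGE_THRESHOLD,
                                partition_seed: int | None = None) -> PrivacyReport:
    """Full privacy report.

    syn->train is the mean over the k subset-level average minimum distances
    (matching the balanced equal-size comparison design, not a pooled
    reference); syn->test is the average minimum distance to the test set.
    Medians pool the per-record minima.  The breach flag trips when the
    coefficient exceeds the threshold — or when syn->train is exactly zero
    (verbatim copies), where the coefficient is undefined.
    """
    if not train_subsets:
        raise ValueError("need at least one training subset")
    per_subset_means = []
    pooled_train_minima = []
    for sub in train_subsets:
        mins = min_distances(syn, sub)
        per_subset_means.append(float(np.mean(mins)))
        pooled_train_minima.append(mins)
    syn_train = float(np.mean(per_subset_means))
    test_minima = min_distances(syn, test)
    syn_test = float(np.mean(test_minima))

    note = ""
    if syn_train == 0:
        coeff = float("inf")
        breach = True
        note = "syn->train distance is zero: synthetic rows duplicate training rows"
    else:
        coeff = leakage_coefficient(syn_test, syn_train)
        breach = coeff > threshold

    baseline_train = baseline_test = None
    if test is not None and train_subsets:
        baseline_train = float(np.mean([
            avg_min_distance(test, sub)[0] for sub in train_subsets]))
        baseline_test = avg_min_distance(train_subsets[0], test)[0]

    exact = None
    if syn_raw is not None and original_raw is not None:
        exact = count_exact_matches(syn_raw, original_raw)

    return PrivacyReport(
        avg_min_dist_syn_train=syn_train,
        avg_min_dist_syn_test=syn_test,
        median_dist_train=float(np.median(np.concatenate(pooled_train_minima))),
        median_dist_test=float(np.median(test_minima)),
        leakage_coefficient=coeff,
        threshold=threshold,
        breach_flag=bool(breach),
        exact_matches=exact,
        baseline_avg_min_train=baseline_train,
        baseline_avg_min_test=baseline_test,
        k_subsets=len(train_subsets),
        partition_seed=partition_seed,
        note=note,
    )


def count_exact_matches(syn: CohortTable, original: CohortTable) -> int:
    """Synthetic rows identical (missing-equals-missing) to >= 1 original row."""
    if syn.schema.names != original.schema.names:
        raise ValueError("schema mismatch")

    def keys(c: CohortTable):
        df = c.df.copy()
        for col in df.columns:
            df[col] = df[col].map(lambda x: MISSING if pd.isna(x) else str(x))
        return df.apply(lambda row: "\x1f".join(row), axis=1)

    original_keys = set(keys(original))
    return int(keys(syn).isin(original_keys).sum())
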