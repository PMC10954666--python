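import numpy as np
import pandas as pd
import pytest

from synthaml import (CohortTable, Schema, VariableSpec, default_config,
                      fit_generator, sample_synthetic, simulate_cohort,
                      split_train_test)

FIXTURE_SEED = 101


def make_cohort(columns: dict, endpoints: dict | None = None,
                label: str = "test") -> CohortTable:
    """Build a small cohort from {name: (kind, values)} pairs."""
    specs = []
    data = {}
    for name, (kind, values) in columns.items():
        if kind == "categorical":
            cats = tuple(sorted({str(v) for v in values if not pd.isna(v)}))
            specs.append(VariableSpec(name, kind, categories=cats + ("na",)))
            data[name] = pd.Series(values, dtype=object)
        elif kind == "time":
            specs.append(VariableSpec(name, kind, pair=columns_pair(name, columns)))
            data[name] = pd.Series(values, dtype=float)
        else:
            specs.append(VariableSpec(name, kind))
            data[name] = pd.Series(values, dtype=float)
    schema = Schema(tuple(specs), endpoints or {})
    cohort = CohortTable(schema, pd.DataFrame(data), label)
    cohort.validate()
    return cohort


def columns_pair(time_name: str, columns: dict) -> str:
    cand = time_name.replace("time", "event")
    if cand in columns:
        return cand
    raise ValueError(f"no event column for {time_name}")


@pytest.fixture(scope="session")
def fixture_pair():
    """Original fixture cohort (n=1606) with its ground truth."""
    return simulate_cohort(default_config(seed=FIXTURE_SEED, n=1606),
                           label="original")


@pytest.fixture(scope="session")
def fixture_cohort(fixture_pair):
    return fixture_pair[0]


@pytest.fixture(scope="session")
def ground_truth(fixture_pair):
    return fixture_pair[1]


@pytest.fixture(scope="session")
def train_test(fixture_cohort):
    return split_train_test(fixture_cohort, 0.8, seed=7)


@pytest.fixture(scope="session")
def fitted_model(train_test):
    return fit_generator(train_test[0], seed=11)


@pytest.fixture(scope="session")
def synthetic_cohort(fitted_model, fixture_cohort):
    return sample_synthetic(fitted_model, fixture_cohort.n, seed=13)


@pytest.fixture(scope="session")
def big_pair():
    """20k-row fixture for Monte-Carlo recovery checks."""
    return simulate_cohort(default_config(seed=FIXTURE_SEED + 1, n=20000),
                           label="big")


@pytest.fixture(scope="session")
def big_cohort(big_pair):
    return big_pair[0]


@pytest.fixture(scope="session")
def big_truth(big_pair):
    return big_pair[1]


@pytest.fixture(scope="session")
def big_model(big_cohort):
    return fit_generator(big_cohort, seed=17)


# ---------------------------------------------------------------------------
# independent brute-force oracles

def km_product_limit_oracle(times, events):
    """Direct product-limit computation: (event_times, survival)."""
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    out_t, out_s = [], []
    s = 1.0
    for u in np.unique(times):
        n_at_risk = np.sum(times >= u)
        d = np.sum((times == u) & (events == 1))
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out_t.append(u)
            out_s.append(s)
    return np.array(out_t), np.array(out_s)


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def hamming_min_oracle(q_labels, r_labels, exclude_self=False):
    """Double-loop minimum Hamming distances."""
    mins = []
    for i, qr in enumerate(q_labels):
        best = np.inf
        for j, rr in enumerate(r_labels):
            if exclude_self and i == j:
                continue
            best = min(best, sum(x != y for x, y in zip(qr, rr)))
        mins.append(best)
    return np.array(mins, float)
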