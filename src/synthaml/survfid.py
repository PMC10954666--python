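"""Normalized survival-fidelity scores for a synthetic cohort.

Three scores per endpoint, each in [0, 1] with 1 meaning the synthetic
cohort's time-to-event behavior matches the original's:

* Kaplan-Meier divergence: 1 minus the time-averaged absolute gap between
  the two survival curves over the original follow-up window;
* optimism: 1 minus |signed area| between the curves — the signed version
  (positive = synthetic survival too favorable) is reported alongside;
* short-sightedness: penalizes a synthetic follow-up horizon shorter than
  the original's; no penalty for overshoot.

Curves are carried forward flat beyond their last observation rather than
extrapolated, mirroring the censoring-plateau behavior of generative models
that stop producing events late in follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import CohortTable
from .survival import km_estimate

__all__ = [
    "SurvivalFidelityReport", "km_divergence_score", "optimism_score",
    "short_sightedness_score", "survival_fidelity_report",
]


@dataclass
class SurvivalFidelityReport:
    endpoint: str
    km_divergence_score: float
    optimism_score: float
    short_sightedness_score: float
    signed_optimism: float
    horizon_real: float
    horizon_syn: float
    grid: str = "union-of-step-times"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _step_integral(real, syn, horizon: float) -> tuple[float, float]:
    """(integral |Sr - Ss|, integral (Ss - Sr)) over [0, horizon] on the
    union grid of step times; both curves flat beyond their last step."""
    cr = km_estimate(*real)
    cs = km_estimate(*syn)
    knots = np.unique(np.concatenate(
        [[0.0], cr.event_times, cs.event_times, [horizon]]))
    knots = knots[(knots >= 0.0) & (knots <= horizon)]
    widths = np.diff(knots)
    left = knots[:-1]
    sr = cr.survival_at(left)
    ss = cs.survival_at(left)
    return float(np.sum(np.abs(sr - ss) * widths)), float(np.sum((ss - sr) * widths))


def _horizon(times) -> float:
    t = np.asarray(times, float)
    return float(t.max()) if t.size else 0.0


def km_divergence_score(real, syn) -> float:
    """1 - (1/T) integral_0^T |S_real - S_syn| dt, T = real max observed time."""
    T = _horizon(real[0])
    if T <= 0:
        raise ValueError("zero-length follow-up in the real cohort")
    d_abs, _ = _step_integral(real, syn, T)
    return float(np.clip(1.0 - d_abs / T, 0.0, 1.0))


def optimism_score(real, syn) -> tuple[float, float]:
    """(signed optimism, score): signed time-averaged S_syn - S_real; the
    score is 1 - |signed|."""
    T = _horizon(real[0])
    if T <= 0:
        raise ValueError("zero-length follow-up in the real cohort")
    _, signed = _step_integral(real, syn, T)
    signed /= T
    return float(signed), float(np.clip(1.0 - abs(signed), 0.0, 1.0))


def short_sightedness_score(real, syn) -> float:
    """1 - max(0, (T_real - T_syn) / T_real) on largest observed times."""
    tr, ts = _horizon(real[0]), _horizon(syn[0])
    if tr <= 0:
        raise ValueError("zero-length follow-up in the real cohort")
    return float(np.clip(1.0 - max(0.0, (tr - ts) / tr), 0.0, 1.0))


def survival_fidelity_report(real: CohortTable, syn: CohortTable,
                             endpoint: str) -> SurvivalFidelityReport:
    rr = real.survival(endpoint)
    ss = syn.survival(endpoint)
    kmd = km_divergence_score(rr, ss)
    signed, opt = optimism_score(rr, ss)
    shs = short_sightedness_score(rr, ss)
    return SurvivalFidelityReport(
        endpoint=endpoint.upper(),
        km_divergence_score=kmd, optimism_score=opt,
        short_sightedness_score=shs, signed_optimism=signed,
        horizon_real=_horizon(rr[0]), horizon_syn=_horizon(ss[0]))
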