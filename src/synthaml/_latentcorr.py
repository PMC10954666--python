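"""Latent (normal-scale) correlation estimation for mixed-type columns.

Pairs are estimated pairwise-complete:

* continuous-continuous: Pearson correlation of van-der-Waerden normal scores;
* continuous-categorical: polyserial moment estimator — exact for a latent
  bivariate normal because E[z1 | z2 in I] = rho * E[z2 | z2 in I];
* categorical-categorical: tetrachoric maximum-likelihood via bisection on
  the bivariate normal CDF.  Variables with K > 2 ordered levels are handled
  by averaging the tetrachorics of all cumulative 2x2 collapses, which
  preserve the latent rho exactly.

All bivariate-normal CDF evaluations and bisections are vectorized across
every (pair, collapse) combination at once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_RHO_MAX = 0.999


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray, n_quad: int = 32) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normals, vectorized.

    Uses Phi(h)Phi(k) + integral_0^rho of the bivariate density at (h, k),
    with Gauss-Legendre quadrature on the correlation path.
    """
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    rho = np.asarray(rho, float)
    x, w = np.polynomial.legendre.leggauss(n_quad)
    r = rho[..., None] * (x + 1.0) / 2.0  # nodes on [0, rho]
    hh, kk = h[..., None], k[..., None]
    one_m = 1.0 - r * r
    dens = np.exp(-(hh * hh - 2.0 * r * hh * kk + kk * kk) / (2.0 * one_m)) / (
        2.0 * np.pi * np.sqrt(one_m))
    integral = (dens * w).sum(axis=-1) * rho / 2.0
    return stats.norm.cdf(h) * stats.norm.cdf(k) + integral


def solve_tetrachoric(h: np.ndarray, k: np.ndarray, p11: np.ndarray,
                      n_iter: int = 60) -> np.ndarray:
    """Solve bvn_cdf(h, k, rho) = p11 for rho, elementwise by bisection.

    bvn_cdf is strictly increasing in rho; out-of-range targets saturate at
    +/-0.999.  Degenerate margins (|h| or |k| infinite) return 0.
    """
    h = np.atleast_1d(np.asarray(h, float))
    k = np.atleast_1d(np.asarray(k, float))
    p11 = np.atleast_1d(np.asarray(p11, float))
    lo = np.full(p11.shape, -_RHO_MAX)
    hi = np.full(p11.shape, _RHO_MAX)
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        above = bvn_cdf(h, k, mid) > p11
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    rho = (lo + hi) / 2.0
    degenerate = ~np.isfinite(h) | ~np.isfinite(k)
    return np.where(degenerate, 0.0, rho)


def normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based van der Waerden scores; NaN preserved."""
    v = np.asarray(values, float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    m = ok.sum()
    if m:
        ranks = stats.rankdata(v[ok], method="average")
        out[ok] = stats.norm.ppf(ranks / (m + 1.0))
    return out


def _thresholds(p: np.ndarray) -> np.ndarray:
    """Category probabilities -> K+1 latent thresholds (-inf, ..., +inf)."""
    cum = np.concatenate([[0.0], np.cumsum(p)])
    cum[-1] = 1.0
    with np.errstate(divide="ignore"):
        return stats.norm.ppf(np.clip(cum, 0.0, 1.0))


def polyserial(z: np.ndarray, codes: np.ndarray, n_cats: int) -> float:
    """Moment polyserial correlation between scores z and coded categories."""
    ok = np.isfinite(z) & (codes >= 0)
    if ok.sum() < 3:
        return 0.0
    z, c = z[ok], codes[ok]
    counts = np.bincount(c, minlength=n_cats).astype(float)
    p = counts / counts.sum()
    if np.count_nonzero(p) < 2:
        return 0.0
    tau = _thresholds(p)
    phi = np.where(np.isfinite(tau), stats.norm.pdf(tau), 0.0)
    dphi = phi[:-1] - phi[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(p > 0, dphi / p, 0.0)
    a = float(np.sum(dphi * dphi / np.where(p > 0, p, 1.0)))
    if a <= 0:
        return 0.0
    rho = float(np.mean(z * m[c]) / a)
    return float(np.clip(rho, -_RHO_MAX, _RHO_MAX))


def latent_correlation(cont_scores: dict[str, np.ndarray],
                       cat_codes: dict[str, tuple[np.ndarray, int]],
                       order: list[str]) -> np.ndarray:
    """Pairwise latent correlation matrix over the named columns.

    cont_scores: name -> normal-score vector (NaN missing).
    cat_codes:   name -> (integer codes with -1 missing, n_categories).
    order:       row/column order of the output.

    Undefined entries (fewer than 3 complete pairs, degenerate margins)
    are set to 0; the result is NOT yet repaired to positive definite.
    """
    d = len(order)
    out = np.eye(d)
    idx = {nm: i for i, nm in enumerate(order)}
    cont_names = [nm for nm in order if nm in cont_scores]
    cat_names = [nm for nm in order if nm in cat_codes]

    # continuous-continuous: pairwise-complete Pearson on scores
    if len(cont_names) >= 2:
        import pandas as pd

        zf = pd.DataFrame({nm: cont_scores[nm] for nm in cont_names})
        cc = zf.corr(min_periods=3).to_numpy()
        for a_i, a in enumerate(cont_names):
            for b_i in range(a_i + 1, len(cont_names)):
                b = cont_names[b_i]
                r = cc[a_i, b_i]
                r = 0.0 if not np.isfinite(r) else float(np.clip(r, -_RHO_MAX, _RHO_MAX))
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = r

    # continuous-categorical: polyserial
    for a in cont_names:
        z = cont_scores[a]
        for b in cat_names:
            codes, K = cat_codes[b]
            r = polyserial(z, codes, K)
            out[idx[a], idx[b]] = out[idx[b], idx[a]] = r

    # categorical-categorical: batched tetrachoric over cumulative collapses
    if len(cat_names) >= 2:
        n = len(next(iter(cat_codes.values()))[0])
        ind_cols, ind_var = [], []
        for nm in cat_names:
            codes, K = cat_codes[nm]
            for s in range(max(1, K - 1)):
                ind_cols.append((codes <= s) & (codes >= 0))
                ind_var.append(nm)
        X = np.asarray(ind_cols, dtype=float).T  # (n, M) cumulative indicators
        V = np.asarray([(cat_codes[nm][0] >= 0) for nm in ind_var], dtype=float).T
        Xz = X * V
        N = V.T @ V
        P11 = Xz.T @ Xz
        CA = Xz.T @ V  # count(A=1 among complete) for pair (i, j)
        h_list, k_list, p_list, pair_list = [], [], [], []
        M = len(ind_var)
        for i in range(M):
            for j in range(i + 1, M):
                if ind_var[i] == ind_var[j]:
                    continue
                nij = N[i, j]
                if nij < 3:
                    continue
                pa, pb, p11 = CA[i, j] / nij, CA[j, i] / nij, P11[i, j] / nij
                if pa <= 0 or pa >= 1 or pb <= 0 or pb >= 1:
                    continue
                h_list.append(stats.norm.ppf(pa))
                k_list.append(stats.norm.ppf(pb))
                p_list.append(p11)
                pair_list.append((ind_var[i], ind_var[j]))
        if pair_list:
            rhos = solve_tetrachoric(np.array(h_list), np.array(k_list), np.array(p_list))
            acc: dict[tuple[str, str], list[float]] = {}
            for (a, b), r in zip(pair_list, rhos):
                acc.setdefault((a, b), []).append(float(r))
            for (a, b), rs in acc.items():
                r = float(np.clip(np.mean(rs), -_RHO_MAX, _RHO_MAX))
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = r
    return out
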