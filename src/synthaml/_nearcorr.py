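"""Nearest positive-definite correlation repair by eigenvalue clipping."""

from __future__ import annotations

import numpy as np


def nearest_correlation(matrix: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``eps`` and rescale to unit diagonal.

    Idempotent on matrices that are already positive definite with unit
    diagonal.  Raises on non-square input.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be a square matrix")
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w.min() >= eps and np.allclose(np.diag(a), 1.0):
        return a
    w = np.clip(w, eps, None)
    b = (v * w) @ v.T
    d = 1.0 / np.sqrt(np.diag(b))
    out = b * np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0
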