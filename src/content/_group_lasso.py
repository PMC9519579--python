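"""Block-coordinate descent for a multi-context group LASSO.

Minimizes  sum_c ||y_c - X_c b_c||^2 / (2 n_c) + lam * sum_m ||B_m.||_2
where block m collects the coefficients of SNP m across all contexts, so a SNP
is either selected jointly for every context or not at all.  Columns are
expected to be standardized per context to unit (population) variance, which
makes every block's curvature the identity and the block update an exact group
soft-threshold.

The solver iterates block updates over an active set (numba-compiled) and
checks the KKT conditions of the inactive blocks with BLAS matrix products,
admitting violators until none remain — the classic working-set strategy of
coordinate-descent LASSO solvers.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep(X, resid, offsets, n_per, B, lam, blocks):
    """One pass of block updates over ``blocks``; returns max coefficient change."""
    C = offsets.size - 1
    maxdiff = 0.0
    s = np.empty(C)
    for bi in range(blocks.size):
        m = blocks[bi]
        snorm2 = 0.0
        for c in range(C):
            a, b = offsets[c], offsets[c + 1]
            dot = 0.0
            for t in range(a, b):
                dot += X[t, m] * resid[t]
            s[c] = dot / n_per[c] + B[m, c]
            snorm2 += s[c] * s[c]
        snorm = np.sqrt(snorm2)
        shrink = 0.0 if snorm <= lam else 1.0 - lam / snorm
        for c in range(C):
            newb = s[c] * shrink
            d = newb - B[m, c]
            if d != 0.0:
                a, b = offsets[c], offsets[c + 1]
                for t in range(a, b):
                    resid[t] -= d * X[t, m]
                B[m, c] = newb
            ad = abs(d)
            if ad > maxdiff:
                maxdiff = ad
    return maxdiff


def _gradients(X, resid, offsets, n_per) -> np.ndarray:
    """Per-block gradient directions s_mc = x_cm' r_c / n_c as an (M, C) array."""
    M = X.shape[1]
    C = offsets.size - 1
    S = np.empty((M, C))
    for c in range(C):
        a, b = offsets[c], offsets[c + 1]
        S[:, c] = X[a:b].T @ resid[a:b] / n_per[c]
    return S


def solve_path(X: np.ndarray, y: np.ndarray, offsets: np.ndarray,
               lambdas: np.ndarray, tol: float = 1e-6,
               max_sweeps: int = 10_000) -> tuple[np.ndarray, bool]:
    """Solve the group LASSO along a decreasing penalty path with warm starts.

    ``X`` is the stacked per-context design (rows of context c are
    ``offsets[c]:offsets[c+1]``), ``y`` the stacked outcomes.  Convergence is
    declared when the largest coefficient change in a sweep falls below
    ``tol`` and no inactive block violates its KKT condition.  Returns
    ``(B_path, converged)`` where ``B_path`` has shape (len(lambdas), M, C).
    """
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    resid = y.copy()
    M = X.shape[1]
    C = offsets.size - 1
    n_per = np.diff(offsets).astype(np.float64)
    B = np.zeros((M, C))
    out = np.empty((lambdas.size, M, C))
    converged = True
    active = np.zeros(M, dtype=bool)
    for li, lam in enumerate(lambdas):
        sweeps = 0
        while True:
            # KKT screening of inactive blocks (BLAS), admit violators
            S = _gradients(X, resid, offsets, n_per)
            norms = np.sqrt((S ** 2).sum(axis=1))
            violators = (~active) & (norms > lam * (1 + 1e-12))
            active |= violators
            blocks = np.flatnonzero(active)
            if blocks.size == 0:
                break
            while sweeps < max_sweeps:
                diff = _sweep(X, resid, offsets, n_per, B, lam, blocks)
                sweeps += 1
                if diff < tol:
                    break
            # blocks shrunk to zero leave the active set
            active = np.any(B != 0, axis=1)
            if not violators.any() or sweeps >= max_sweeps:
                break
        if sweeps >= max_sweeps:
            converged = False
        out[li] = B
    return out, converged


def lambda_max(X: np.ndarray, y: np.ndarray, offsets: np.ndarray) -> float:
    """Smallest penalty at which every block is zero."""
    n_per = np.diff(offsets).astype(np.float64)
    S = _gradients(np.asarray(X, float), np.asarray(y, float), offsets, n_per)
    return float(np.sqrt((S ** 2).sum(axis=1)).max())
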