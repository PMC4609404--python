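"""Batch orthogonal matching pursuit (Gram/Cholesky formulation).

Codes many signals against one dictionary using only the Gram matrix
``G = D^T D`` and the correlations ``A0 = D^T X``, maintaining a growing
Cholesky factor per signal so no least-squares system is re-solved from
scratch.  Selection stops at ``L`` atoms or when the squared residual
(tracked as ``||x||^2 - gamma . a0[idx]``, exact for the orthogonal
projection) falls below a per-signal threshold.  The inner loop is
numba-compiled; the first call in a process pays the JIT cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["batch_omp"]


@njit(cache=True)
def _batch_omp_core(G, A0, L, norms2, tol2, out):  # pragma: no cover - jitted
    K, S = A0.shape
    Lmat = np.zeros((L, L))
    w = np.zeros(L)
    gamma = np.zeros(L)
    idx = np.zeros(L, dtype=np.int64)
    for s in range(S):
        if norms2[s] <= tol2[s]:
            continue
        a0 = A0[:, s]
        a = a0.copy()
        n_active = 0
        for n in range(L):
            # most correlated unselected atom
            best = -1
            best_val = 0.0
            for k in range(K):
                v = abs(a[k])
                if v > best_val:
                    taken = False
                    for m in range(n_active):
                        if idx[m] == k:
                            taken = True
                            break
                    if not taken:
                        best = k
                        best_val = v
            if best < 0 or best_val < 1e-12:
                break
            # extend the Cholesky factor of G[idx, idx]
            if n_active == 0:
                Lmat[0, 0] = 1.0
            else:
                for m in range(n_active):
                    acc = G[idx[m], best]
                    for t in range(m):
                        acc -= Lmat[m, t] * w[t]
                    w[m] = acc / Lmat[m, m]
                sq = 1.0
                for m in range(n_active):
                    sq -= w[m] * w[m]
                if sq <= 1e-12:
                    break  # linearly dependent selection
                for m in range(n_active):
                    Lmat[n_active, m] = w[m]
                Lmat[n_active, n_active] = np.sqrt(sq)
            idx[n_active] = best
            n_active += 1
            # solve L L^T gamma = a0[idx]
            for m in range(n_active):
                acc = a0[idx[m]]
                for t in range(m):
                    acc -= Lmat[m, t] * gamma[t]
                gamma[m] = acc / Lmat[m, m]
            for m in range(n_active - 1, -1, -1):
                acc = gamma[m]
                for t in range(m + 1, n_active):
                    acc -= Lmat[t, m] * gamma[t]
                gamma[m] = acc / Lmat[m, m]
            # residual of the orthogonal projection
            eps = norms2[s]
            for m in range(n_active):
                eps -= gamma[m] * a0[idx[m]]
            if eps <= tol2[s]:
                break
            # a = a0 - G[:, idx] @ gamma
            for k in range(K):
                acc = a0[k]
                for m in range(n_active):
                    acc -= G[k, idx[m]] * gamma[m]
                a[k] = acc
        for m in range(n_active):
            out[idx[m], s] = gamma[m]


def batch_omp(atoms: np.ndarray, X: np.ndarray, L: int,
              tol_rel: float = 0.0, tol_abs: float = 0.0) -> np.ndarray:
    """OMP codes for all signal columns of ``X``.

    Selection stops at ``L`` atoms or when the residual norm drops below
    ``max(tol_abs, tol_rel * ||x||)`` for that signal (signals already
    below the threshold get an empty code).  Assumes unit-norm atoms (the
    Cholesky seed uses ``G_kk = 1``).  Returns the dense ``(K, S)``
    coefficient matrix.
    """
    atoms = np.ascontiguousarray(atoms, dtype=np.float64)
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    G = atoms.T @ atoms
    A0 = np.ascontiguousarray(atoms.T @ X)
    norms2 = np.einsum("ij,ij->j", X, X)
    tol2 = np.maximum((tol_rel * tol_rel) * norms2, tol_abs * tol_abs)
    out = np.zeros_like(A0)
    _batch_omp_core(G, A0, min(L, atoms.shape[1]), norms2, tol2, out)
    return out
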