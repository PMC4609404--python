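"""Overlapping patch operators, OMP sparse coding and K-SVD training.

Patches of ``N0 x N0`` pixels are extracted on a regular grid with a given
stride (stride 1 = fully overlapping).  Patch s corresponds to a binary
extraction operator ``E_s``; the regularizer of the dictionary-based
reconstructions is ``sum_s ||E_s mu - D alpha_s||^2`` with an overcomplete
dictionary ``D`` (unit-norm atoms) and codes ``alpha_s`` that are at most
``L``-sparse.

DC convention: patches are coded with their mean removed and the mean is
restored on reassembly, so atoms are not spent on the DC component and a
constant image is reproduced exactly by extract -> code -> accumulate.

The heavy batch coding path delegates to scikit-learn's Gram-based OMP;
:func:`omp_code` is a self-contained single-vector OMP used for small
problems and as the reference implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._omp import batch_omp

__all__ = [
    "PatchScheme",
    "PatchDictionary",
    "extract_patches",
    "patch_adjoint_accumulate",
    "patch_coverage",
    "omp_code",
    "omp_batch",
    "dct_dictionary",
    "ksvd_train",
    "train_global_dictionary",
    "save_dictionary",
    "load_dictionary",
    "atom_mosaic",
]


@dataclass(frozen=True)
class PatchScheme:
    """Patch extraction grid: ``N0 x N0`` patches every ``stride`` pixels."""

    patch_size: int
    stride: int
    image_n: int

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.patch_size <= self.image_n):
            raise ValueError("require 1 <= stride <= patch_size <= image_n")

    @property
    def n_per_axis(self) -> int:
        return (self.image_n - self.patch_size) // self.stride + 1

    @property
    def n_patches(self) -> int:
        return self.n_per_axis ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2


@dataclass
class PatchDictionary:
    """Overcomplete patch dictionary with unit-norm atoms.

    ``atoms`` has shape ``(N0*N0, K)``; column ``d_k`` is one atom.
    """

    atoms: np.ndarray
    patch_size: int

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.shape[0] != self.patch_size ** 2:
            raise ValueError("atom length must equal patch_size**2")
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero-norm atom")
        self.atoms = self.atoms / norms

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    def gram(self) -> np.ndarray:
        return self.atoms.T @ self.atoms


def extract_patches(mu: np.ndarray, scheme: PatchScheme) -> np.ndarray:
    """All patches of ``mu`` as columns of a ``(N0*N0, S)`` matrix.

    Column ``s`` (row-major over the patch grid) equals ``E_s mu``; each
    patch is flattened row-major.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (scheme.image_n, scheme.image_n):
        raise ValueError("image does not match scheme")
    n0, st = scheme.patch_size, scheme.stride
    win = np.lib.stride_tricks.sliding_window_view(mu, (n0, n0))[::st, ::st]
    m = scheme.n_per_axis
    return win.reshape(m * m, n0 * n0).T.copy()


def patch_adjoint_accumulate(values: np.ndarray, scheme: PatchScheme
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint of patch extraction: ``sum_s E_s^T v_s`` plus coverage counts.

    Returns ``(image, q)`` where ``q[r, c]`` is the number of patches
    covering pixel ``(r, c)`` (the quadratic coefficient of the patch
    regularizer for binary extraction operators).
    """
    n0, st, n = scheme.patch_size, scheme.stride, scheme.image_n
    m = scheme.n_per_axis
    values = np.asarray(values, dtype=float)
    if values.shape != (n0 * n0, m * m):
        raise ValueError("patch matrix does not match scheme")
    vals = values.T.reshape(m, m, n0, n0)
    out = np.zeros((n, n))
    q = np.zeros((n, n))
    for a in range(n0):
        for b in range(n0):
            sl = (slice(a, a + st * m, st) if st > 1 else slice(a, a + m),
                  slice(b, b + st * m, st) if st > 1 else slice(b, b + m))
            out[sl] += vals[:, :, a, b]
            q[sl] += 1.0
    return out, q


def patch_coverage(scheme: PatchScheme) -> np.ndarray:
    """Per-pixel patch coverage counts ``q`` as an image."""
    ones = np.ones((scheme.patch_dim, scheme.n_patches))
    _, q = patch_adjoint_accumulate(ones, scheme)
    return q


def omp_code(D: PatchDictionary | np.ndarray, x: np.ndarray, L: int,
             tol_rel: float = 1e-6) -> np.ndarray:
    """Orthogonal matching pursuit for one signal.

    Greedily selects the atom most correlated with the residual, re-fits all
    active coefficients by least squares, and stops after ``L`` atoms or when
    the residual norm drops below ``tol_rel * ||x||``.  Returns the dense
    coefficient vector (at most ``L`` nonzeros).
    """
    if L < 1:
        raise ValueError("sparsity level L must be >= 1")
    atoms = D.atoms if isinstance(D, PatchDictionary) else np.asarray(D, float)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != atoms.shape[0]:
        raise ValueError("signal length does not match atoms")
    k = atoms.shape[1]
    alpha = np.zeros(k)
    xnorm = np.linalg.norm(x)
    if xnorm == 0:
        return alpha
    active: list[int] = []
    resid = x.copy()
    for _ in range(min(L, k)):
        corr = np.abs(atoms.T @ resid)
        corr[active] = -1.0  # never reselect
        idx = int(np.argmax(corr))
        active.append(idx)
        sub = atoms[:, active]
        coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
        resid = x - sub @ coef
        if np.linalg.norm(resid) <= tol_rel * xnorm:
            break
    alpha[active] = coef
    return alpha


def omp_batch(D: PatchDictionary | np.ndarray, X: np.ndarray, L: int,
              tol_rel: float = 0.0, tol_abs: float = 0.0) -> np.ndarray:
    """Batch OMP coding of signal columns ``X``.

    Gram/Cholesky ("batch OMP") formulation; stops per signal at ``L``
    atoms or at residual ``max(tol_abs, tol_rel * ||x||)``.  Returns the
    dense ``(K, S)`` coefficient matrix.
    """
    atoms = D.atoms if isinstance(D, PatchDictionary) else np.asarray(D, float)
    return batch_omp(atoms, np.asarray(X, dtype=float), L,
                     tol_rel=tol_rel, tol_abs=tol_abs)


def dct_dictionary(patch_size: int, n_atoms: int) -> PatchDictionary:
    """Overcomplete separable DCT dictionary (the usual K-SVD seed)."""
    m = int(np.ceil(np.sqrt(n_atoms)))
    n = np.arange(patch_size)
    basis = np.cos(np.pi * np.outer(np.arange(m), n) / m)  # m 1-D waves
    basis[1:] -= basis[1:].mean(axis=1, keepdims=True)
    basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    atoms = np.einsum("ap,bq->pqab", basis, basis).reshape(patch_size ** 2, m * m)
    return PatchDictionary(atoms=atoms[:, :n_atoms], patch_size=patch_size)


def _reseed_unused(atoms: np.ndarray, X: np.ndarray, resid_norms: np.ndarray,
                   unused: np.ndarray) -> None:
    """Replace unused atoms with the worst-represented signals (lowest index
    wins ties), in place."""
    order = np.argsort(-resid_norms, kind="stable")
    for slot, k in enumerate(np.flatnonzero(unused)):
        src = X[:, order[slot % order.size]]
        nrm = np.linalg.norm(src)
        if nrm == 0:
            continue
        atoms[:, k] = src / nrm


def ksvd_train(patches: np.ndarray, K: int, L: int, n_iters: int = 20,
               seed: int | None = None,
               init: PatchDictionary | np.ndarray | None = None,
               min_usage: int | None = None,
               dup_coherence: float = 0.99) -> tuple[PatchDictionary, np.ndarray]:
    """K-SVD dictionary learning on signal columns ``patches``.

    Alternates batch OMP coding with per-atom rank-1 SVD updates of the
    restricted residual (the atom and its coefficients are replaced by the
    leading singular pair, which is optimal for the support and keeps the
    training objective non-increasing over the atom sweep).  A clearing
    step re-seeds atoms that are used by fewer than ``min_usage`` signals
    (default: 10% of the expected per-atom share ``n_signals * L / K``,
    at least 4) or nearly duplicate another atom (coherence above
    ``dup_coherence``) from the worst-represented signals, lowest atom
    index first.

    Returns ``(dictionary, codes)`` with codes from a final coding pass.
    """
    X = np.asarray(patches, dtype=float)
    n_feat, n_sig = X.shape
    if n_sig < K:
        raise ValueError("need at least K training signals")
    if not np.any(np.linalg.norm(X, axis=0) > 0):
        raise ValueError("degenerate (all-zero) training set")
    if min_usage is None:
        min_usage = max(4, round(0.1 * n_sig * L / K))
    rng = np.random.default_rng(seed)

    if init is None:
        nz = np.flatnonzero(np.linalg.norm(X, axis=0) > 1e-12)
        pick = rng.choice(nz, size=K, replace=nz.size < K)
        atoms = X[:, pick].copy()
        atoms /= np.linalg.norm(atoms, axis=0)
    else:
        atoms = (init.atoms if isinstance(init, PatchDictionary) else
                 np.asarray(init, float)).copy()
        if atoms.shape != (n_feat, K):
            raise ValueError("init dictionary shape mismatch")

    codes = np.zeros((K, n_sig))
    for _ in range(max(n_iters, 1)):
        codes = omp_batch(atoms, X, L)
        resid = X - atoms @ codes
        usage = (codes != 0).sum(axis=1)
        for k in range(K):
            support = np.flatnonzero(codes[k])
            if support.size == 0:
                continue
            # restricted residual including atom k's own contribution
            e = resid[:, support] + np.outer(atoms[:, k], codes[k, support])
            u, s, vt = np.linalg.svd(e, full_matrices=False)
            atoms[:, k] = u[:, 0]
            codes[k, support] = s[0] * vt[0]
            resid[:, support] = e - np.outer(atoms[:, k], codes[k, support])
        # clearing step
        gram = np.abs(atoms.T @ atoms)
        np.fill_diagonal(gram, 0.0)
        stale = usage < min_usage
        for k in range(K):
            if not stale[k]:
                high = gram[k] > dup_coherence
                high[:k + 1] = False
                stale |= high
        if np.any(stale):
            _reseed_unused(atoms, X, np.linalg.norm(resid, axis=0), stale)

    codes = omp_batch(atoms, X, L)
    return PatchDictionary(atoms=atoms, patch_size=int(round(np.sqrt(n_feat)))), codes


def save_dictionary(path, D: PatchDictionary) -> None:
    """Write a dictionary as a plain matrix file with a small header."""
    with open(path, "w") as fh:
        fh.write(f"# dictsir dictionary patch_size={D.patch_size} "
                 f"n_atoms={D.n_atoms}\n")
        np.savetxt(fh, D.atoms)


def load_dictionary(path) -> PatchDictionary:
    with open(path) as fh:
        header = fh.readline()
        fields = dict(tok.split("=") for tok in header.split()
                      if "=" in tok)
        atoms = np.loadtxt(fh)
    return PatchDictionary(atoms.reshape(-1, int(fields["n_atoms"])),
                           int(fields["patch_size"]))


def atom_mosaic(D: PatchDictionary, window: tuple[float, float] = (-1.0, 1.0)
                ) -> np.ndarray:
    """8-bit tile mosaic of the atoms (row-major), one-pixel separators,
    displayed in the given window."""
    n0 = D.patch_size
    m = int(np.ceil(np.sqrt(D.n_atoms)))
    lo, hi = window
    out = np.zeros((m * (n0 + 1) + 1, m * (n0 + 1) + 1), dtype=np.uint8)
    for k in range(D.n_atoms):
        r, c = divmod(k, m)
        tile = D.atoms[:, k].reshape(n0, n0)
        scaled = np.clip((tile - lo) / (hi - lo), 0.0, 1.0) * 255.0
        out[1 + r * (n0 + 1):1 + r * (n0 + 1) + n0,
            1 + c * (n0 + 1):1 + c * (n0 + 1) + n0] = np.rint(scaled)
    return out


def train_global_dictionary(reference: np.ndarray, scheme: PatchScheme,
                            K: int = 256, L: int = 5, n_iters: int = 20,
                            seed: int | None = None,
                            max_train_patches: int = 10000) -> PatchDictionary:
    """Train a global dictionary from the overlapping patches of a reference
    image (the fixed-dictionary reconstruction mode).

    Patch means are removed before training; near-constant patches carry no
    structure and are dropped.  At most ``max_train_patches`` patches are
    used (seeded subsample) to keep training tractable.
    """
    X = extract_patches(reference, scheme)
    X = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    keep = norms > 1e-10 * max(1.0, norms.max())
    if keep.sum() < K:
        raise ValueError("reference image has too few non-constant patches")
    X = X[:, keep]
    rng = np.random.default_rng(seed)
    if X.shape[1] > max_train_patches:
        X = X[:, rng.choice(X.shape[1], size=max_train_patches, replace=False)]
    D, _ = ksvd_train(X, K=K, L=L, n_iters=n_iters, seed=seed,
                      init=dct_dictionary(scheme.patch_size, K))
    return D
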