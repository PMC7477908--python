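"""Orthogonal Matching Pursuit for complex-valued signals.

Greedy atom selection by maximum |<residual, atom>| with a full
least-squares refit on the selected support at every step.  A plain
single-vector routine serves as the reference; ``sparse_code_all`` runs
the same recursion vectorized across all patch columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SparseCodeMatrix", "omp", "sparse_code_all"]

# residual norms at or below this (relative) level count as an exact fit
_ZERO_TOL = 1e-12


@dataclass
class SparseCodeMatrix:
    """n x N matrix of sparse patch codes, at most ``sparsity_cap`` nonzeros each."""

    data: np.ndarray  # (n, N)
    sparsity_cap: int
    per_column_nnz: np.ndarray  # (N,) ints

    @property
    def n_atoms(self) -> int:
        return self.data.shape[0]

    @property
    def n_signals(self) -> int:
        return self.data.shape[1]


def _check_dictionary(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D)
    if D.ndim != 2:
        raise ValueError("dictionary must be a 2-D array")
    norms = np.linalg.norm(D, axis=0)
    if (norms < _ZERO_TOL).any():
        raise ValueError("dictionary contains a zero-norm atom")
    if np.abs(norms - 1.0).max() > 1e-6:
        raise ValueError("dictionary atoms must be unit-norm")
    return D


def omp(D: np.ndarray, y: np.ndarray, T0: int, tol: float = 0.0) -> np.ndarray:
    """Sparse-code one vector against dictionary ``D``.

    Stops after ``T0`` atoms or once the residual 2-norm drops to ``tol``
    (default 0: pure sparsity-capped form).  Ties in the correlation
    magnitude break toward the lowest atom index.
    """
    D = _check_dictionary(D)
    y = np.asarray(y).ravel()
    m, n = D.shape
    if y.shape[0] != m:
        raise ValueError(f"signal length {y.shape[0]} != atom length {m}")
    if T0 < 1:
        raise ValueError("T0 must be >= 1")
    if tol < 0:
        raise ValueError("tol must be non-negative")

    code = np.zeros(n, dtype=np.result_type(D.dtype, y.dtype, np.float64))
    stop = max(tol, _ZERO_TOL * max(1.0, np.linalg.norm(y)))
    residual = y.astype(code.dtype, copy=True)
    support: list[int] = []
    for _ in range(min(T0, m)):
        if np.linalg.norm(residual) <= stop:
            break
        corr = D.conj().T @ residual
        j = int(np.argmax(np.abs(corr)))  # argmax keeps the lowest index on ties
        if j in support:
            break
        support.append(j)
        sub = D[:, support]
        coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ coef
    if support:
        code[support] = coef
    return code


def sparse_code_all(
    D: np.ndarray, patches, T0: int, tol: float = 0.0
) -> SparseCodeMatrix:
    """OMP-code every column of a patch matrix (vectorized batch recursion).

    Equivalent column-by-column to :func:`omp`; the batch version shares
    the Gram matrix across columns and solves the per-support normal
    equations with stacked small systems.
    """
    D = _check_dictionary(D)
    Y = patches.data if isinstance(getattr(patches, "data", None), np.ndarray) else np.asarray(patches)
    if Y.ndim != 2 or Y.shape[0] != D.shape[0]:
        raise ValueError("patch matrix rows must match the atom length")
    if T0 < 1:
        raise ValueError("T0 must be >= 1")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    m, n = D.shape
    N = Y.shape[1]
    dtype = np.result_type(D.dtype, Y.dtype, np.complex128 if np.iscomplexobj(Y) or np.iscomplexobj(D) else np.float64)
    D = D.astype(dtype, copy=False)
    Y = Y.astype(dtype, copy=False)
    T = min(T0, m)

    G = D.conj().T @ D  # (n, n) shared Gram
    DtY = D.conj().T @ Y  # (n, N)
    Dt = np.ascontiguousarray(D.T)  # row-contiguous for fast atom gathers
    codes = np.zeros((n, N), dtype=dtype)
    nnz = np.zeros(N, dtype=np.int64)
    support = np.zeros((T, N), dtype=np.int64)
    coef = np.zeros((T, N), dtype=dtype)

    residual = Y.copy()
    stop = np.maximum(tol, _ZERO_TOL * np.maximum(1.0, np.linalg.norm(Y, axis=0)))
    active = np.linalg.norm(residual, axis=0) > stop

    for t in range(T):
        if not active.any():
            break
        whole = bool(active.all())
        ia = slice(None) if whole else np.flatnonzero(active)
        Ra = residual if whole else residual[:, ia]
        corr = D.conj().T @ Ra  # (n, Na)
        # squared modulus preserves the argmax and skips the sqrt
        support[t, ia] = np.argmax(corr.real**2 + corr.imag**2, axis=0)
        nnz[ia] = t + 1

        S = support[: t + 1, ia]  # (t+1, Na)
        rhs = np.take_along_axis(DtY[:, ia], S, axis=0)  # (t+1, Na)
        Gs = G[S.T[:, :, None], S.T[:, None, :]]  # (Na, t+1, t+1)
        # tiny ridge guards against numerically repeated atoms
        Gs = Gs + (1e-13 * np.eye(t + 1, dtype=dtype))
        c = np.linalg.solve(Gs, rhs.T[:, :, None])  # (Na, t+1, 1)
        coef[: t + 1, ia] = c[:, :, 0].T

        Dg = Dt[S.T]  # (Na, t+1, m)
        approx = (c.transpose(0, 2, 1) @ Dg)[:, 0, :].T  # (m, Na)
        Ya = Y if whole else Y[:, ia]
        residual[:, ia] = Ya - approx
        active[ia] = np.linalg.norm(residual[:, ia], axis=0) > stop[ia]

    valid = np.arange(T)[:, None] < nnz[None, :]  # (T, N) entries actually set
    codes[support[valid], np.nonzero(valid)[1]] = coef[valid]
    return SparseCodeMatrix(data=codes, sparsity_cap=T0, per_column_nnz=nnz)
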