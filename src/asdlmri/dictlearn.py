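"""Dictionary initialization and Approximate K-SVD updates.

One dictionary-learning pass (``dl_iterate``) = sparse-code every training
column, then sweep the atoms once with the approximate rank-1 update:
for each atom, refit the atom direction against the residual restricted
to the signals using it, renormalize, then refit those signals'
coefficients.  Atoms used by no signal are replaced by the currently
worst-represented training column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .omp import SparseCodeMatrix, sparse_code_all

__all__ = ["Dictionary", "init_dictionary", "aksvd_atom_sweep", "dl_iterate"]

_UNIT_TOL = 1e-9


@dataclass
class Dictionary:
    """m x n matrix of unit-norm atoms; n adapts over iterations."""

    atoms: np.ndarray  # (m, n), unit-norm columns
    sorted_by_power: bool = False

    @property
    def m(self) -> int:
        return self.atoms.shape[0]

    @property
    def n(self) -> int:
        return self.atoms.shape[1]

    def check_unit_norm(self) -> None:
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.abs(norms - 1.0).max() > _UNIT_TOL * 10:
            raise ValueError("dictionary atoms are not unit-norm")


def _as_matrix(patches) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        return patches
    data = getattr(patches, "data", None)
    return data if isinstance(data, np.ndarray) else np.asarray(patches)


def init_dictionary(patches, n_init: int, seed: int = 0) -> Dictionary:
    """Initial dictionary from the left singular vectors of the training data.

    The first min(n_init, m, rank) atoms are the left singular vectors in
    decreasing singular-value order; any remaining slots are filled with
    randomly chosen training columns normalized to unit norm.
    """
    Y = _as_matrix(patches)
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    norms = np.linalg.norm(Y, axis=0)
    if not (norms > 0).any():
        raise ValueError("cannot initialize a dictionary from all-zero training data")
    m = Y.shape[0]
    U, svals, _ = np.linalg.svd(Y, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * max(Y.shape) * np.finfo(float).eps))
    k = min(n_init, m, rank)
    atoms = [U[:, :k]]
    if n_init > k:
        rng = np.random.default_rng(seed)
        usable = np.flatnonzero(norms > 0)
        picks = rng.choice(usable, size=n_init - k, replace=usable.size < n_init - k)
        extra = Y[:, picks] / norms[picks]
        atoms.append(extra)
    D = np.concatenate(atoms, axis=1)
    D = D / np.linalg.norm(D, axis=0, keepdims=True)
    return Dictionary(atoms=D.astype(np.result_type(Y.dtype, np.float64)))


def aksvd_atom_sweep(
    D: Dictionary, patches, codes: SparseCodeMatrix
) -> tuple[Dictionary, SparseCodeMatrix]:
    """One approximate K-SVD sweep over all atoms (ascending index).

    Each atom is re-estimated from the residual of the signals that use it
    (one atom-then-coefficients alternation of the rank-1 subproblem);
    the corresponding code entries are refit immediately.  Unused atoms
    are replaced by the worst-represented training column, normalized.
    """
    Y = _as_matrix(patches)
    A = D.atoms.copy()
    X = codes.data.copy()
    m, n = A.shape
    if Y.shape[0] != m or X.shape[0] != n or X.shape[1] != Y.shape[1]:
        raise ValueError("dictionary, patches and codes have inconsistent shapes")

    E = Y - A @ X  # running full residual, updated in place per atom
    for j in range(n):
        xj = X[j]
        used = np.flatnonzero(xj)
        if used.size == 0:
            # replacement rule: worst-represented training column, ties -> lowest
            col_err = np.linalg.norm(E, axis=0)
            worst = int(np.argmax(col_err))
            nrm = np.linalg.norm(Y[:, worst])
            if nrm > 0:
                A[:, j] = Y[:, worst] / nrm
            continue
        Ej = E[:, used] + np.outer(A[:, j], xj[used])
        d = Ej @ xj[used].conj()
        nrm = np.linalg.norm(d)
        if nrm <= 1e-14:
            # degenerate residual: keep the old atom direction
            d = A[:, j]
        else:
            d = d / nrm
        x_new = d.conj() @ Ej  # least-squares row coefficients for unit-norm d
        E[:, used] = Ej - np.outer(d, x_new)
        A[:, j] = d
        X[j, used] = x_new

    nnz = np.count_nonzero(X, axis=0)
    return (
        Dictionary(atoms=A, sorted_by_power=False),
        SparseCodeMatrix(
            data=X, sparsity_cap=codes.sparsity_cap, per_column_nnz=nnz
        ),
    )


def dl_iterate(
    patches, D: Dictionary, T0: int, tol: float = 0.0
) -> tuple[Dictionary, SparseCodeMatrix]:
    """One full dictionary-learning pass: sparse coding + AK-SVD atom sweep."""
    codes = sparse_code_all(D.atoms, patches, T0=T0, tol=tol)
    return aksvd_atom_sweep(D, patches, codes)
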