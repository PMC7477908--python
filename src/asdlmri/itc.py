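"""Information-theoretic criteria for choosing the dictionary size.

Candidate sizes are nested sub-dictionaries of one learned, power-sorted
dictionary; for each size h the representation RMSE of the first h atoms
(with the existing codes truncated, no re-coding) is combined with a
complexity count P = s*N + (m-1)*n through either the extended BIC or the
extended renormalized-maximum-likelihood criterion, and the minimizing
size n_ITC is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .dictlearn import Dictionary
from .omp import SparseCodeMatrix

__all__ = [
    "ITCEvaluation",
    "representation_rmse",
    "model_complexity",
    "ebic",
    "erml",
    "atom_powers",
    "sort_dictionary_by_power",
    "select_candidate_size",
]


@dataclass
class ITCEvaluation:
    """Criterion values over the candidate sizes and the selected n_ITC."""

    candidate_sizes: np.ndarray  # increasing ints within [n_min, n]
    criterion_values: np.ndarray  # same length
    criterion_kind: str  # "ebic" | "erml"
    n_itc: int
    Q: int  # m * N
    s: int


def _as_matrix(obj) -> np.ndarray:
    if isinstance(obj, np.ndarray):
        return obj
    if isinstance(getattr(obj, "atoms", None), np.ndarray):
        return obj.atoms
    if isinstance(getattr(obj, "data", None), np.ndarray):
        return obj.data
    return np.asarray(obj)


def representation_rmse(Y, D, X) -> float:
    """(1/sqrt(Q)) * ||Y - D X||_F with Q = m*N."""
    Ym = _as_matrix(Y)
    if Ym.size == 0:
        raise ValueError("empty training matrix")
    E = Ym - _as_matrix(D) @ _as_matrix(X)
    return float(np.linalg.norm(E) / np.sqrt(Ym.size))


def model_complexity(s: int, N: int, m: int, n: int) -> int:
    """P = s*N + (m-1)*n: nonzeros in the codes plus free dictionary entries."""
    if min(s, N, m, n) < 0:
        raise ValueError("all arguments must be non-negative")
    return s * N + (m - 1) * n


def _log_binom(n: int, s: int) -> float:
    return float(gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1))


def ebic(rmse: float, Q: int, P_complexity: int, N: int, n: int, s: int) -> float:
    """Extended Bayesian information criterion for one candidate size.

    2*log(rmse) + (log(Q)/Q)*P + (2N/Q)*log C(n, s); the binomial term
    accounts for the possible support positions of the nonzero code
    entries.  Natural logarithms; the log-binomial goes through
    log-gamma for numerical range.
    """
    if Q <= 0:
        raise ValueError("Q must be positive")
    if n < s:
        raise ValueError(f"candidate size n={n} smaller than sparsity s={s}")
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    if rmse == 0:
        warnings.warn("EBIC of a perfect fit: returning -inf", RuntimeWarning)
        return -np.inf
    return (
        2.0 * np.log(rmse)
        + (np.log(Q) / Q) * P_complexity
        + (2.0 * N / Q) * _log_binom(n, s)
    )


def erml(
    rmse: float,
    Q: int,
    P_complexity: int,
    N: int,
    n: int,
    s: int,
    dx_frob_sq: float,
) -> float:
    """Extended renormalized-maximum-likelihood criterion.

    (Q-P)*log(rmse^2/(Q-P)) + P*log(||DX||_F^2/(Q*P)) + log[P*(Q-P)]
    + 2N*log C(n, s).  Candidates with Q <= P are over-parameterized and
    reported as +inf (infeasible, never selected).
    """
    P = P_complexity
    if n < s:
        raise ValueError(f"candidate size n={n} smaller than sparsity s={s}")
    if Q <= P:
        return np.inf
    if rmse <= 0 or dx_frob_sq <= 0:
        warnings.warn("ERML needs positive rmse and ||DX||^2: returning -inf", RuntimeWarning)
        return -np.inf
    return (
        (Q - P) * np.log(rmse**2 / (Q - P))
        + P * np.log(dx_frob_sq / (Q * P))
        + np.log(P * (Q - P))
        + 2.0 * N * _log_binom(n, s)
    )


def atom_powers(X) -> np.ndarray:
    """Per-atom importance: the 2-norm of each code row across all signals."""
    Xm = _as_matrix(X)
    return np.linalg.norm(Xm, axis=1)


def sort_dictionary_by_power(
    D: Dictionary, X: SparseCodeMatrix
) -> tuple[Dictionary, SparseCodeMatrix, np.ndarray]:
    """Reorder atoms (and code rows) by non-increasing power; D X is unchanged."""
    powers = atom_powers(X)
    perm = np.argsort(-powers, kind="stable")
    D_sorted = Dictionary(atoms=D.atoms[:, perm], sorted_by_power=True)
    X_sorted = SparseCodeMatrix(
        data=X.data[perm, :],
        sparsity_cap=X.sparsity_cap,
        per_column_nnz=X.per_column_nnz,
    )
    return D_sorted, X_sorted, perm


def candidate_size_grid(n: int, n_min: int, m: int, n_cand: int) -> np.ndarray:
    """Evenly spaced integer candidate sizes over [max(n_min, m), n]."""
    lo = max(n_min, m)
    if n < lo:
        raise ValueError(f"current size n={n} below the candidate floor {lo}")
    if n - lo + 1 <= n_cand:
        return np.arange(lo, n + 1)
    return np.unique(np.round(np.linspace(lo, n, n_cand)).astype(int))


def select_candidate_size(
    D: Dictionary,
    X: SparseCodeMatrix,
    Y,
    s: int,
    n_min: int,
    n_cand: int,
    kind: str = "ebic",
    recode: bool = False,
    n_eval: int | None = None,
    seed: int = 0,
) -> ITCEvaluation:
    """Evaluate the criterion over nested sub-dictionary sizes and pick n_ITC.

    ``D`` must already be power-sorted; the size-h candidate keeps the
    first h atoms.  Two ways of scoring a candidate are supported:

    * ``recode=False`` (default): the size-h error keeps the existing
      codes truncated to their first h rows.  The residual norms are
      accumulated by adding the dropped atoms' rank-1 contributions back
      onto the full residual, so the scan costs about one matrix product.
    * ``recode=True``: each candidate sub-dictionary re-codes the signals
      with OMP at sparsity ``s`` (on a seeded subsample of at most
      ``n_eval`` columns when given), measuring what the smaller
      dictionary could actually achieve.  This is the mode the size
      controller uses: a redundant dictionary spreads representation
      power over all atoms, so truncated codes overstate the cost of
      shrinking.

    Ties select the smallest size.
    """
    if kind not in ("ebic", "erml"):
        raise ValueError(f"unknown criterion kind {kind!r}")
    if not D.sorted_by_power:
        raise ValueError("dictionary must be sorted by atom power first")
    Ym = _as_matrix(Y)
    A = D.atoms
    Xd = X.data
    m, n = A.shape
    sizes = candidate_size_grid(n, n_min, m, n_cand)

    if recode:
        from .omp import sparse_code_all

        if n_eval is not None and n_eval < Ym.shape[1]:
            cols = np.random.default_rng(seed).choice(
                Ym.shape[1], size=n_eval, replace=False
            )
            Ym = Ym[:, cols]
        N = Ym.shape[1]
        Q = m * N
        err_sq = {}
        dx_sq = {}
        for h in sizes:
            ch = sparse_code_all(A[:, :h], Ym, T0=s)
            approx = A[:, :h] @ ch.data
            err_sq[int(h)] = float(np.linalg.norm(Ym - approx) ** 2)
            dx_sq[int(h)] = float(np.vdot(approx, approx).real)
    else:
        N = Ym.shape[1]
        Q = m * N
        E = Ym - A @ Xd
        err_sq = {}
        dx_sq = {}
        cur = n
        for h in sizes[::-1]:
            while cur > h:
                cur -= 1
                E = E + np.outer(A[:, cur], Xd[cur])
            err_sq[int(h)] = float(np.vdot(E, E).real)
        for h in sizes:
            if kind == "erml":
                approx = A[:, : int(h)] @ Xd[: int(h)]
                dx_sq[int(h)] = float(np.vdot(approx, approx).real)

    values = np.empty(len(sizes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, h in enumerate(sizes):
            rmse = np.sqrt(max(err_sq[int(h)], 0.0) / Q)
            P = model_complexity(s, N, m, int(h))
            if kind == "ebic":
                values[i] = ebic(rmse, Q, P, N, int(h), s)
            else:
                values[i] = erml(rmse, Q, P, N, int(h), s, dx_sq[int(h)])
    n_itc = int(sizes[int(np.argmin(values))])
    return ITCEvaluation(
        candidate_sizes=sizes,
        criterion_values=values,
        criterion_kind=kind,
        n_itc=n_itc,
        Q=Q,
        s=s,
    )
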