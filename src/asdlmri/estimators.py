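"""scikit-learn style estimators for adaptive-size dictionary learning.

``AdaptiveDictionaryLearning`` follows the sklearn decomposition API
(``fit`` on an (n_samples, n_features) signal matrix, ``transform`` to
sparse codes, ``components_`` holding the learned atoms) while supporting
complex-valued signals, which the stock sklearn dictionary learners do
not.  It therefore composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dictlearn import dl_iterate, init_dictionary
from .omp import sparse_code_all
from .sizecontrol import SizeControllerState, adaptation_step

__all__ = ["AdaptiveDictionaryLearning", "OMPSparseCoder"]


def _validate_signals(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of shape (n_samples, n_features)")
    if X.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    return X


class OMPSparseCoder(TransformerMixin, BaseEstimator):
    """Sparse-code signals against a fixed dictionary with complex-capable OMP.

    Parameters
    ----------
    dictionary : ndarray of shape (n_features, n_atoms)
        Unit-norm atoms.
    sparsity_cap : int, default=6
        Maximum nonzeros per code (T0).
    tol : float, default=0.0
        Optional residual-norm stopping tolerance per signal.
    """

    def __init__(self, dictionary=None, sparsity_cap: int = 6, tol: float = 0.0):
        self.dictionary = dictionary
        self.sparsity_cap = sparsity_cap
        self.tol = tol

    def fit(self, X, y=None):
        if self.dictionary is None:
            raise ValueError("OMPSparseCoder requires a dictionary")
        self.dictionary_ = np.asarray(self.dictionary)
        self.n_features_in_ = self.dictionary_.shape[0]
        return self

    def transform(self, X):
        if not hasattr(self, "dictionary_"):
            self.fit(X)
        X = _validate_signals(X)
        codes = sparse_code_all(
            self.dictionary_, X.T, T0=self.sparsity_cap, tol=self.tol
        )
        return codes.data.T


class AdaptiveDictionaryLearning(TransformerMixin, BaseEstimator):
    """Dictionary learning whose atom count is selected by an information criterion.

    Alternates OMP sparse coding with approximate K-SVD atom sweeps.
    After each pass (during the search phase) the atoms are sorted by
    power, nested sub-dictionary sizes are scored with EBIC or ERML, and
    the size is nudged toward the criterion minimizer: a large gap shrinks
    it by ``e_minus``, a small gap by one, and a minimizer equal to the
    current size grows it by ``e_plus`` random atoms.  After
    ``search_iters`` passes the size freezes at the last minimizer and
    ``refine_iters`` further passes polish the atoms.

    Parameters
    ----------
    n_init : int, default=128
        Initial atom count (left singular vectors of the training data,
        padded with random training signals).
    n_min : int, default=64
        Smallest admissible dictionary size.
    n_cand : int, default=20
        Number of candidate sizes scored per evaluation.
    sparsity_cap : int, default=6
        OMP sparsity cap T0.
    itc_sparsity : int, default=5
        Sparsity s entering the complexity count of the criteria.
    criterion : {"ebic", "erml"}, default="ebic"
    e_minus, e_plus, gap_threshold : int, default=5
        Size-update steps and the gap separating the two shrink rules.
    search_iters : int, default=20
        Learning passes during which the size adapts.
    refine_iters : int, default=5
        Fixed-size passes after freezing.
    tol : float, default=0.0
        OMP residual stopping tolerance.
    random_state : int or None

    Attributes
    ----------
    dictionary_ : ndarray (n_features, n_components_)
        Learned unit-norm atoms (power-sorted).
    components_ : ndarray (n_components_, n_features)
        sklearn-convention view of the atoms.
    n_components_ : int
        The frozen, criterion-selected dictionary size.
    size_trajectory_ : list of dict
        Per-iteration record of (iteration, n, n_itc, action, criterion).
    """

    def __init__(
        self,
        n_init: int = 128,
        n_min: int = 64,
        n_cand: int = 20,
        sparsity_cap: int = 6,
        itc_sparsity: int = 5,
        criterion: str = "ebic",
        e_minus: int = 5,
        e_plus: int = 5,
        gap_threshold: int = 5,
        search_iters: int = 20,
        refine_iters: int = 5,
        itc_recode: bool = True,
        itc_eval_cols: int = 512,
        tol: float = 0.0,
        random_state=None,
    ):
        self.n_init = n_init
        self.n_min = n_min
        self.n_cand = n_cand
        self.sparsity_cap = sparsity_cap
        self.itc_sparsity = itc_sparsity
        self.criterion = criterion
        self.e_minus = e_minus
        self.e_plus = e_plus
        self.gap_threshold = gap_threshold
        self.search_iters = search_iters
        self.refine_iters = refine_iters
        self.itc_recode = itc_recode
        self.itc_eval_cols = itc_eval_cols
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        """Learn an adaptively sized dictionary from signals (rows of X)."""
        X = _validate_signals(X)
        Y = X.T  # (n_features, n_samples) internally
        seed = int(np.random.default_rng(self.random_state).integers(2**31 - 1))
        D = init_dictionary(Y, self.n_init, seed=seed)
        state = SizeControllerState(
            n_current=D.n,
            n_min=self.n_min,
            e_minus=self.e_minus,
            e_plus=self.e_plus,
            gap_threshold=self.gap_threshold,
            search_iters=self.search_iters,
            refine_iters=self.refine_iters,
            seed=seed,
        )
        trajectory: list[dict] = []
        codes = None
        total = self.search_iters + self.refine_iters
        for it in range(max(total, 1)):
            D, codes = dl_iterate(Y, D, T0=self.sparsity_cap, tol=self.tol)
            if not state.frozen:
                D, codes, ev, action = adaptation_step(
                    D,
                    codes,
                    Y,
                    state,
                    s=self.itc_sparsity,
                    n_cand=self.n_cand,
                    kind=self.criterion,
                    recode=self.itc_recode,
                    n_eval=self.itc_eval_cols,
                )
                crit = float(
                    ev.criterion_values[
                        int(np.flatnonzero(ev.candidate_sizes == ev.n_itc)[0])
                    ]
                )
                trajectory.append(
                    {
                        "iteration": it,
                        "n": state.n_current,
                        "n_itc": ev.n_itc,
                        "action": action,
                        "criterion": crit,
                    }
                )
            else:
                trajectory.append(
                    {
                        "iteration": it,
                        "n": state.n_current,
                        "n_itc": state.n_itc_last,
                        "action": "refine",
                        "criterion": np.nan,
                    }
                )
        self.dictionary_ = D.atoms
        self.components_ = D.atoms.T
        self.n_components_ = D.n
        self.n_features_in_ = X.shape[1]
        self.size_trajectory_ = trajectory
        self.controller_state_ = state
        self.n_iter_ = max(total, 1)
        return self

    def transform(self, X):
        """Sparse-code signals against the learned dictionary."""
        if not hasattr(self, "dictionary_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        X = _validate_signals(X)
        codes = sparse_code_all(
            self.dictionary_, X.T, T0=self.sparsity_cap, tol=self.tol
        )
        return codes.data.T
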