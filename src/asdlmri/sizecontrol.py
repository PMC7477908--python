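"""Dictionary-size adaptation driven by the criterion minimizer n_ITC.

Three-rule update per learning iteration: a large gap between the current
size n and n_ITC shrinks by e_minus, a small positive gap shrinks by one,
and n_ITC = n grows by e_plus (new atoms drawn at random).  After a fixed
number of search iterations the size is frozen at the last n_ITC and a
few refinement iterations run at that size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictlearn import Dictionary
from .omp import SparseCodeMatrix

__all__ = [
    "SizeControllerState",
    "adapt_size",
    "resize_dictionary",
    "step_and_maybe_freeze",
    "adaptation_step",
]


@dataclass
class SizeControllerState:
    """Mutable controller state carried across dictionary-learning iterations."""

    n_current: int
    n_min: int
    e_minus: int = 5
    e_plus: int = 5
    gap_threshold: int = 5
    search_iters: int = 20
    refine_iters: int = 5
    n_itc_last: int = field(default=0)
    iter_count: int = 0
    frozen: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_current < self.n_min:
            raise ValueError("n_current must be >= n_min")
        if self.n_itc_last == 0:
            self.n_itc_last = self.n_current


def adapt_size(
    state: SizeControllerState, n_itc: int, n_min: int | None = None
) -> tuple[int, str]:
    """Apply the three-rule size update; returns (new_n, action).

    Actions: ``shrink_big`` (gap > gap_threshold, drop e_minus atoms),
    ``shrink_one`` (small gap), ``grow`` (n_ITC = n, add e_plus atoms).
    The new size never drops below n_min.
    """
    if state.frozen:
        raise ValueError("size controller is frozen; no further adaptation")
    n = state.n_current
    if n_itc > n:
        raise ValueError(f"n_ITC={n_itc} exceeds the current size n={n}")
    floor = state.n_min if n_min is None else n_min
    gap = n - n_itc
    if gap > state.gap_threshold:
        return max(n - state.e_minus, floor), "shrink_big"
    if gap > 0:
        return max(n - 1, floor), "shrink_one"
    return n + state.e_plus, "grow"


def resize_dictionary(
    D: Dictionary,
    X: SparseCodeMatrix,
    new_n: int,
    training_patches=None,
    seed: int = 0,
    n_min: int = 1,
) -> tuple[Dictionary, SparseCodeMatrix]:
    """Shrink to the leading atoms or grow with random unit-norm atoms.

    Shrinking keeps the first ``new_n`` atoms and code rows (the
    dictionary is expected to be power-sorted, so the least important
    atoms are dropped).  Growing appends seeded Gaussian atoms normalized
    to unit norm, with zero-initialized code rows.
    """
    if new_n < n_min:
        raise ValueError(f"new size {new_n} below the minimum {n_min}")
    n = D.n
    if new_n == n:
        return D, X
    if new_n < n:
        atoms = D.atoms[:, :new_n].copy()
        data = X.data[:new_n].copy()
    else:
        rng = np.random.default_rng(seed)
        fresh = rng.standard_normal((D.m, new_n - n))
        if np.iscomplexobj(D.atoms):
            fresh = fresh + 1j * rng.standard_normal((D.m, new_n - n))
        fresh = fresh / np.linalg.norm(fresh, axis=0, keepdims=True)
        atoms = np.concatenate([D.atoms, fresh.astype(D.atoms.dtype)], axis=1)
        data = np.concatenate(
            [X.data, np.zeros((new_n - n, X.data.shape[1]), dtype=X.data.dtype)]
        )
    return (
        Dictionary(atoms=atoms, sorted_by_power=D.sorted_by_power and new_n < n),
        SparseCodeMatrix(
            data=data,
            sparsity_cap=X.sparsity_cap,
            per_column_nnz=np.count_nonzero(data, axis=0),
        ),
    )


def adaptation_step(
    D: Dictionary,
    codes: SparseCodeMatrix,
    Y,
    state: SizeControllerState,
    *,
    s: int,
    n_cand: int,
    kind: str = "ebic",
    recode: bool = True,
    n_eval: int | None = 512,
):
    """One full size-adaptation move after a dictionary-learning pass.

    Sorts the atoms by power, evaluates the criterion over the candidate
    sizes (re-coding each candidate by default, on a signal subsample of
    at most ``n_eval`` columns), advances the controller (freezing it at
    the end of the search phase) and resizes the dictionary accordingly.
    Returns ``(D, codes, evaluation, action)``.
    """
    from .itc import select_candidate_size, sort_dictionary_by_power

    D, codes, _ = sort_dictionary_by_power(D, codes)
    ev = select_candidate_size(
        D,
        codes,
        Y,
        s=s,
        n_min=state.n_min,
        n_cand=n_cand,
        kind=kind,
        recode=recode,
        n_eval=n_eval,
        seed=state.seed + state.iter_count,
    )
    state.n_itc_last = ev.n_itc
    step_and_maybe_freeze(state)
    if state.frozen:
        action = "freeze"
        if state.n_current < D.n:
            D, codes = resize_dictionary(
                D, codes, state.n_current, n_min=state.n_min
            )
    else:
        new_n, action = adapt_size(state, ev.n_itc)
        state.n_current = new_n
        D, codes = resize_dictionary(
            D,
            codes,
            new_n,
            seed=state.seed + state.iter_count,
            n_min=state.n_min,
        )
    return D, codes, ev, action


def step_and_maybe_freeze(state: SizeControllerState) -> SizeControllerState:
    """Advance the iteration counter; freeze at n_ITC once the search phase ends.

    On freezing, the last n_ITC (clamped at n_min) becomes the final
    dictionary size; subsequent refinement iterations leave it unchanged.
    """
    state.iter_count += 1
    if not state.frozen and state.iter_count >= state.search_iters:
        state.frozen = True
        state.n_current = max(state.n_itc_last, state.n_min)
    return state
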