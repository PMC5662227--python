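"""Brute-force ground truth: absorption probabilities of the finite chain.

The mutant-count process lives on the grid (n_s, n_d) in
[0, N_S] x [0, N_D] — at most (N_S+1)(N_D+1) states with at most five
nonzero one-step probabilities each.  Fixation probabilities are harmonic
functions of the jump chain and come from a single sparse linear solve;
this is exact up to linear-algebra round-off and is the reference against
which both the generating-function solution and the Monte-Carlo simulator
are judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import (
    ModelParameters,
    PopulationState,
    transition_probabilities,
    validate_parameters,
)

__all__ = [
    "StateSpace",
    "build_transition_matrix",
    "absorption_probability",
    "absorption_probabilities",
    "absorption_profile",
]

# beyond this many states the direct sparse factorization is replaced by an
# iterative solve
_DIRECT_SOLVE_LIMIT = 250_001


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of the full (n_s, n_d) grid with a flat index map."""

    n_stem: int
    n_diff: int
    states: tuple[PopulationState, ...] = field(repr=False, default=())

    @classmethod
    def build(cls, params: ModelParameters) -> "StateSpace":
        states = tuple(
            PopulationState(i, j)
            for i in range(params.n_stem + 1)
            for j in range(params.n_diff + 1)
        )
        return cls(params.n_stem, params.n_diff, states)

    @property
    def size(self) -> int:
        return (self.n_stem + 1) * (self.n_diff + 1)

    def index(self, state: PopulationState) -> int:
        i, j = state
        if not (0 <= i <= self.n_stem and 0 <= j <= self.n_diff):
            raise ValueError(f"state {state} outside the grid")
        return i * (self.n_diff + 1) + j

    def state(self, k: int) -> PopulationState:
        return self.states[k]

    def absorbing(self, params: ModelParameters) -> list[PopulationState]:
        """All absorbing states of the chain under ``params``; always
        contains (0, 0) and (N_S, N_D)."""
        out = []
        for corner in (
            PopulationState(0, 0),
            PopulationState(self.n_stem, self.n_diff),
            PopulationState(self.n_stem, 0),
            PopulationState(0, self.n_diff),
        ):
            w = transition_probabilities(params, corner)
            if w.ws_plus == w.ws_minus == w.wd_plus == w.wd_minus == 0.0:
                if corner not in out:
                    out.append(corner)
        return out


def build_transition_matrix(params: ModelParameters) -> sp.csr_matrix:
    """Row-stochastic one-step matrix over the full state grid (self-loops
    included; absorbing rows are identity rows)."""
    p = validate_parameters(params)
    space = StateSpace.build(p)
    nd1 = p.n_diff + 1
    rows, cols, vals = [], [], []
    for k, (i, j) in enumerate(space.states):
        w = transition_probabilities(p, PopulationState(i, j))
        moves = (
            ((i + 1) * nd1 + j, w.ws_plus),
            ((i - 1) * nd1 + j, w.ws_minus),
            (i * nd1 + (j + 1), w.wd_plus),
            (i * nd1 + (j - 1), w.wd_minus),
        )
        for kk, wv in moves:
            if wv > 0.0:
                rows.append(k)
                cols.append(kk)
                vals.append(wv)
        if w.w_none > 0.0:
            rows.append(k)
            cols.append(k)
            vals.append(w.w_none)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(space.size, space.size)
    )
    return mat


def _solve_absorption(params: ModelParameters, target: PopulationState) -> np.ndarray:
    """Absorption probabilities into ``target`` from every state.

    Self-loops are eliminated first (off-diagonal row normalization): the
    absorption probabilities of the embedded jump chain are identical and
    the linear system is better conditioned.
    """
    p = validate_parameters(params)
    space = StateSpace.build(p)
    nd1 = p.n_diff + 1
    n = space.size

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    diag = np.ones(n)
    for k, (i, j) in enumerate(space.states):
        w = transition_probabilities(p, PopulationState(i, j))
        tot = w.ws_plus + w.ws_minus + w.wd_plus + w.wd_minus
        if tot == 0.0:  # absorbing
            b[k] = 1.0 if (i, j) == tuple(target) else 0.0
            continue
        for kk, wv in (
            ((i + 1) * nd1 + j, w.ws_plus),
            ((i - 1) * nd1 + j, w.ws_minus),
            (i * nd1 + (j + 1), w.wd_plus),
            (i * nd1 + (j - 1), w.wd_minus),
        ):
            if wv > 0.0:
                rows.append(k)
                cols.append(kk)
                vals.append(-wv / tot)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)) + sp.diags(diag)
    if n <= _DIRECT_SOLVE_LIMIT:
        h = spla.spsolve(A.tocsc(), b)
    else:
        h, info = spla.lgmres(A, b, rtol=1e-12, atol=0.0, maxiter=20_000)
        if info != 0:
            raise RuntimeError(f"iterative absorption solve failed (info={info})")
    return h


def absorption_probabilities(params: ModelParameters) -> np.ndarray:
    """Fixation probability h(i, j) (absorption into (N_S, N_D)) for every
    state, as an array of shape (N_S + 1, N_D + 1)."""
    p = params
    h = _solve_absorption(p, PopulationState(p.n_stem, p.n_diff))
    return h.reshape(p.n_stem + 1, p.n_diff + 1)


def absorption_probability(params: ModelParameters, i: int, j: int) -> float:
    """Fixation probability of the whole system starting from ``(i, j)``."""
    h = absorption_probabilities(params)
    if not (0 <= i <= params.n_stem and 0 <= j <= params.n_diff):
        raise ValueError(f"initial state ({i}, {j}) outside the grid")
    return float(np.clip(h[i, j], 0.0, 1.0))


def absorption_profile(
    params: ModelParameters, i: int, j: int
) -> dict[PopulationState, float]:
    """Absorption mass into every absorbing state from ``(i, j)``.

    With extra absorbing corners (e.g. u2 = eta1 = 0 makes (N_S, 0) a trap)
    the whole-system fixation mass h(N_S, N_D) no longer tells the full
    story; this surfaces where the remaining probability ends up.
    """
    p = validate_parameters(params)
    space = StateSpace.build(p)
    out = {}
    for target in space.absorbing(p):
        h = _solve_absorption(p, target)
        out[target] = float(np.clip(h[space.index(PopulationState(i, j))], 0.0, 1.0))
    return out
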