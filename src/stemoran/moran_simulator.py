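"""Monte-Carlo realization of the birth-death process.

The estimation protocol follows the study design: batches of 20,000
realizations run to absorption (with a safety cap of 15,000 update steps),
repeated five times with independent RNG streams; the point estimate is the
mean batch fixation fraction and the quoted error is the standard deviation
of the batch means.

Two samplers are provided.  The literal chain draws one of five outcomes
(four moves plus self-replacement) per update; the embedded-chain mode
skips the self-loops — absorption probabilities are invariant under
de-looping — and advances the step clock by the expected sojourn 1/W_tot,
so censoring against the step cap remains comparable.  Batches are
simulated as a whole with vectorized numpy updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .model_core import (
    ModelParameters,
    PopulationState,
    transition_probabilities,
    validate_parameters,
)

__all__ = [
    "SimulationConfig",
    "SimulationEstimate",
    "AbsorptionRecord",
    "step",
    "run_to_absorption",
    "estimate_fixation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol settings for fixation estimation.

    ``t_max`` counts update steps (events, self-replacements included) by
    default; with ``t_max_is_continuous`` it is read as continuous time and
    converted via the step duration 1/(N_S + N_D).  Censored runs count as
    non-fixed unless ``exclude_censored`` is set.
    """

    n_realizations: int = 20_000
    t_max: float = 15_000
    n_repeats: int = 5
    seed: int | None = None
    use_embedded_chain: bool = False
    exclude_censored: bool = False
    t_max_is_continuous: bool = False

    def __post_init__(self):
        if self.n_realizations < 1 or self.n_repeats < 1 or self.t_max <= 0:
            raise ValueError("n_realizations, n_repeats >= 1 and t_max > 0 required")

    def step_cap(self, params: ModelParameters) -> float:
        if self.t_max_is_continuous:
            return self.t_max * params.n_tot
        return self.t_max


@dataclass(frozen=True)
class SimulationEstimate:
    """Monte-Carlo fixation estimate with repeat-based error.

    ``stderr`` is the sample standard deviation of the per-repeat fixation
    fractions (0 when only one repeat was run).
    """

    rho_hat: float
    stderr: float
    n_fixed: int
    n_extinct: int
    n_censored: int
    seed: int | None
    per_repeat: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if not (0.0 <= self.rho_hat <= 1.0) or self.stderr < 0:
            raise ValueError("rho_hat must be in [0,1] and stderr >= 0")


class AbsorptionRecord(NamedTuple):
    """Outcome of a single realization: 'fixed', 'extinct', 'extinct-other'
    (trapped in an extra absorbing state) or 'censored', plus the number of
    update steps consumed."""

    outcome: str
    steps: int


def step(
    params: ModelParameters, state: PopulationState, rng: np.random.Generator
) -> PopulationState:
    """Sample one update of the chain from a non-absorbing ``state``."""
    w = transition_probabilities(params, state)
    if w.ws_plus == w.ws_minus == w.wd_plus == w.wd_minus == 0.0:
        raise ValueError(f"step() called on absorbing state {state}")
    u = rng.random()
    ns, nd = state
    if u < w.ws_plus:
        return PopulationState(ns + 1, nd)
    u -= w.ws_plus
    if u < w.ws_minus:
        return PopulationState(ns - 1, nd)
    u -= w.ws_minus
    if u < w.wd_plus:
        return PopulationState(ns, nd + 1)
    u -= w.wd_plus
    if u < w.wd_minus:
        return PopulationState(ns, nd - 1)
    return state


def run_to_absorption(
    params: ModelParameters,
    initial: PopulationState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AbsorptionRecord:
    """Iterate single updates until absorption or the step cap."""
    p = validate_parameters(params)
    state = initial
    cap = config.step_cap(p)
    n_steps = 0
    while n_steps < cap:
        w = transition_probabilities(p, state)
        if w.ws_plus == w.ws_minus == w.wd_plus == w.wd_minus == 0.0:
            return AbsorptionRecord(_classify(p, state), n_steps)
        state = step(p, state, rng)
        n_steps += 1
    w = transition_probabilities(p, state)
    if w.ws_plus == w.ws_minus == w.wd_plus == w.wd_minus == 0.0:
        return AbsorptionRecord(_classify(p, state), n_steps)
    return AbsorptionRecord("censored", n_steps)


def _classify(p: ModelParameters, state: PopulationState) -> str:
    if state == (p.n_stem, p.n_diff):
        return "fixed"
    if state == (0, 0):
        return "extinct"
    return "extinct-other"


def _run_batch(
    params: ModelParameters,
    initial: PopulationState,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Vectorized batch: returns (n_fixed, n_extinct, n_other, n_censored)."""
    p = params
    NS, ND = p.n_stem, p.n_diff
    cap = config.step_cap(p)
    embedded = config.use_embedded_chain

    ns = np.full(n, initial.n_s, dtype=np.int64)
    nd = np.full(n, initial.n_d, dtype=np.int64)
    clock = np.zeros(n)
    active = np.ones(n, dtype=bool)
    n_fixed = n_extinct = n_other = 0

    while active.any():
        idx = np.flatnonzero(active)
        s = ns[idx]
        d = nd[idx]
        nr = p.r1 * (NS - s) + p.r2 * s + p.rt1 * (ND - d) + p.rt2 * d
        wsp = (p.r2 * (1 - p.u2) * s + p.rt2 * p.eta2 * d) / nr * (NS - s) / NS
        wsm = (p.r1 * (1 - p.u1) * (NS - s)
               + p.rt1 * p.eta1 * (ND - d)) / nr * s / NS
        wdp = (p.rt2 * (1 - p.eta2) * d + p.r2 * p.u2 * s) / nr * (ND - d) / ND
        wdm = (p.rt1 * (1 - p.eta1) * (ND - d)
               + p.r1 * p.u1 * (NS - s)) / nr * d / ND
        tot = wsp + wsm + wdp + wdm

        trapped = tot <= 0.0
        if trapped.any():
            ti = idx[trapped]
            n_fixed += int(np.sum((ns[ti] == NS) & (nd[ti] == ND)))
            n_extinct += int(np.sum((ns[ti] == 0) & (nd[ti] == 0)))
            n_other += int(np.sum(~(((ns[ti] == NS) & (nd[ti] == ND))
                                    | ((ns[ti] == 0) & (nd[ti] == 0)))))
            active[ti] = False
            keep = ~trapped
            idx, wsp, wsm, wdp, wdm, tot = (
                a[keep] for a in (idx, wsp, wsm, wdp, wdm, tot)
            )
            if idx.size == 0:
                continue

        u = rng.random(idx.size)
        if embedded:
            u = u * tot
            clock[idx] += 1.0 / tot  # expected sojourn incl. self-loops
        else:
            clock[idx] += 1.0
        c1 = wsp
        c2 = c1 + wsm
        c3 = c2 + wdp
        c4 = c3 + wdm
        ns[idx] += np.where(u < c1, 1, 0) - np.where((u >= c1) & (u < c2), 1, 0)
        nd[idx] += np.where((u >= c2) & (u < c3), 1, 0) \
            - np.where((u >= c3) & (u < c4), 1, 0)

        done_fix = (ns[idx] == NS) & (nd[idx] == ND)
        done_ext = (ns[idx] == 0) & (nd[idx] == 0)
        n_fixed += int(done_fix.sum())
        n_extinct += int(done_ext.sum())
        active[idx[done_fix | done_ext]] = False

        timed_out = clock[idx] >= cap
        censor = timed_out & ~(done_fix | done_ext)
        if censor.any():
            active[idx[censor]] = False
    n_censored = n - n_fixed - n_extinct - n_other
    return n_fixed, n_extinct, n_other, n_censored


def estimate_fixation(
    params: ModelParameters,
    initial: PopulationState,
    config: SimulationConfig,
) -> SimulationEstimate:
    """Estimate the fixation probability from ``initial`` by the batch
    protocol of ``config``.

    The root seed is expanded into independent per-repeat streams with
    ``numpy.random.SeedSequence.spawn``, so repeats are independent yet the
    whole estimate is reproducible from (seed, config).
    """
    p = validate_parameters(params)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    fractions = []
    tot_fixed = tot_extinct = tot_other = tot_censored = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        f, e, o, c = _run_batch(p, initial, config.n_realizations, config, rng)
        tot_fixed += f
        tot_extinct += e
        tot_other += o
        tot_censored += c
        denom = config.n_realizations - (c if config.exclude_censored else 0)
        fractions.append(f / denom if denom else 0.0)
    total = config.n_realizations * config.n_repeats
    if tot_censored / total > 1e-3:
        warnings.warn(
            f"{tot_censored}/{total} runs censored at the step cap "
            f"{config.step_cap(p):g}; fixation fractions are biased low",
            stacklevel=2,
        )
    fr = np.asarray(fractions)
    stderr = float(np.std(fr, ddof=1)) if len(fr) > 1 else 0.0
    return SimulationEstimate(
        rho_hat=float(fr.mean()),
        stderr=stderr,
        n_fixed=tot_fixed,
        n_extinct=tot_extinct + tot_other,
        n_censored=tot_censored,
        seed=config.seed,
        per_repeat=tuple(fr.tolist()),
    )
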