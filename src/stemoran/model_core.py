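"""Parameters, states and one-step transition probabilities of the
four-compartment Moran process.

Two genotypes (wild type = 1, mutant = 2) compete inside two phenotype
compartments of fixed size: a stem-cell (SC) niche of ``n_stem`` cells and a
non-stem / differentiated (DC) compartment of ``n_diff`` cells.  At every
update one cell is chosen to reproduce proportional to its division rate;
the offspring either stays in the parent's compartment or crosses over —
SC offspring differentiate with probability ``u`` and DC offspring
dedifferentiate back into the niche with probability ``eta`` — and replaces
a uniformly chosen cell of the destination compartment (including, possibly,
a cell of its own type, which is a no-op).

The mutant copy numbers ``(n_s, n_d)`` form a bivariate birth-death chain
whose one-step move probabilities are computed here; everything downstream
(exact fixation, the Markov oracle, the simulator) consumes these.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ParameterError",
    "AbsorbingStateWarning",
    "ModelParameters",
    "PopulationState",
    "TransitionProbabilities",
    "validate_parameters",
    "differentiation_from_split",
    "apply_death_rates",
    "total_fitness",
    "transition_probabilities",
    "is_absorbing",
    "extra_absorbing_states",
]

_PARAM_KEYS = (
    "n_stem", "n_diff", "r1", "r2", "rt1", "rt2", "u1", "u2", "eta1", "eta2",
)


class ParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


class AbsorbingStateWarning(UserWarning):
    """Emitted when parameter choices create absorbing states besides
    all-mutant and all-wild-type (e.g. the SC niche can fill with mutants
    that can never be displaced)."""


@dataclass(frozen=True)
class ModelParameters:
    """All rates and sizes of the four-compartment model.

    Attributes
    ----------
    n_stem, n_diff
        Compartment sizes N_S (stem) and N_D (non-stem), both >= 1.
    r1, r2
        Division rates of wild-type / mutant stem cells.
    rt1, rt2
        Division rates of wild-type / mutant non-stem cells.
    u1, u2
        Per-division differentiation probabilities (SC offspring enters the
        DC compartment) for each genotype, in [0, 1].
    eta1, eta2
        Per-division dedifferentiation probabilities (DC offspring becomes
        stem-like and enters the SC niche), in [0, 1].
    """

    n_stem: int
    n_diff: int
    r1: float = 1.0
    r2: float = 1.0
    rt1: float = 1.0
    rt2: float = 1.0
    u1: float = 0.0
    u2: float = 0.0
    eta1: float = 0.0
    eta2: float = 0.0

    @property
    def n_tot(self) -> int:
        return self.n_stem + self.n_diff

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _PARAM_KEYS}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        unknown = set(data) - set(_PARAM_KEYS)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        if "n_stem" not in data or "n_diff" not in data:
            raise ParameterError("n_stem and n_diff are required")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))

    def to_toml(self) -> str:
        # flat key = value lines; repr round-trips floats losslessly
        lines = []
        for k in _PARAM_KEYS:
            v = getattr(self, k)
            lines.append(f"{k} = {v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "ModelParameters":
        import tomllib

        return cls.from_dict(tomllib.loads(text))


class PopulationState(NamedTuple):
    """Mutant copy numbers (n_s in the SC niche, n_d in the DC compartment).

    Wild-type counts are the complements N_S - n_s and N_D - n_d.
    """

    n_s: int
    n_d: int


class TransitionProbabilities(NamedTuple):
    """One-step move probabilities of the bivariate birth-death chain.

    ``ws_plus``/``ws_minus`` change the mutant SC count by +/-1,
    ``wd_plus``/``wd_minus`` the mutant DC count; ``w_none`` is the
    complementary self-replacement (no-change) probability.  The five
    components sum to 1 by construction.
    """

    ws_plus: float
    ws_minus: float
    wd_plus: float
    wd_minus: float
    w_none: float


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Check all parameter invariants; return ``params`` unchanged.

    Raises :class:`ParameterError` on violations.  Emits an
    :class:`AbsorbingStateWarning` when the parameters create absorbing
    states other than extinction (0, 0) and fixation (N_S, N_D) — the
    whole-system fixation problem is then ill-posed for downstream solvers.
    """
    p = params
    if not (isinstance(p.n_stem, int) and isinstance(p.n_diff, int)):
        raise ParameterError("compartment sizes must be integers")
    if p.n_stem < 1 or p.n_diff < 1:
        raise ParameterError("compartment sizes must be >= 1")
    for name in ("r1", "r2", "rt1", "rt2"):
        v = getattr(p, name)
        if not math.isfinite(v) or v < 0:
            raise ParameterError(f"rate {name}={v} must be finite and >= 0")
    if p.r1 == p.r2 == p.rt1 == p.rt2 == 0:
        raise ParameterError("at least one division rate must be positive")
    for name in ("u1", "u2", "eta1", "eta2"):
        v = getattr(p, name)
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"probability {name}={v} must lie in [0, 1]")
    extra = extra_absorbing_states(p)
    if extra:
        warnings.warn(
            f"extra absorbing states exist at {extra}; whole-system fixation "
            "from an interior state may be unreachable",
            AbsorbingStateWarning,
            stacklevel=2,
        )
    return p


def differentiation_from_split(u_hat: float, v_hat: float) -> float:
    """Effective differentiation probability u = u_hat + 2*v_hat.

    ``u_hat`` is the probability of a symmetric differentiation (both
    offspring non-stem) and ``v_hat`` of an asymmetric division (one stem,
    one non-stem offspring); only the combination enters the dynamics.
    """
    if u_hat < 0 or v_hat < 0:
        raise ParameterError("split probabilities must be non-negative")
    u = u_hat + 2.0 * v_hat
    if u > 1.0:
        raise ParameterError(
            f"effective differentiation probability {u} exceeds 1"
        )
    return u


def apply_death_rates(
    params: ModelParameters,
    d_s1: float,
    d_s2: float,
    d_d1: float,
    d_d2: float,
) -> ModelParameters:
    """Fold per-type death rates into the division rates (r -> r/d).

    Unequal death rates act on the dynamics only through the ratio of
    division to death rate, so they are absorbed at construction and never
    carried separately downstream.
    """
    for name, d in (("d_s1", d_s1), ("d_s2", d_s2), ("d_d1", d_d1), ("d_d2", d_d2)):
        if d <= 0:
            raise ParameterError(f"death rate {name}={d} must be positive")
    return params.replace(
        r1=params.r1 / d_s1,
        r2=params.r2 / d_s2,
        rt1=params.rt1 / d_d1,
        rt2=params.rt2 / d_d2,
    )


def total_fitness(params: ModelParameters, state: PopulationState) -> float:
    """Total reproductive weight N_r of the whole population at ``state``."""
    p = params
    ns, nd = state
    _check_state(p, state)
    nr = (
        p.r1 * (p.n_stem - ns)
        + p.r2 * ns
        + p.rt1 * (p.n_diff - nd)
        + p.rt2 * nd
    )
    if nr <= 0.0:
        raise ParameterError(
            f"total fitness is zero at state {state}: no cell can reproduce"
        )
    return nr


def transition_probabilities(
    params: ModelParameters, state: PopulationState
) -> TransitionProbabilities:
    """One-step move probabilities of the mutant-count chain at ``state``.

    The reproducing cell is drawn proportional to its rate (weight / N_r);
    the replaced cell is drawn uniformly from the destination compartment,
    including cells of the reproducing type — hence the (N - n)/N and n/N
    factors, and a nonzero no-change probability.
    """
    p = params
    ns, nd = state
    nr = total_fitness(p, state)

    ws_plus = (p.r2 * (1 - p.u2) * ns + p.rt2 * p.eta2 * nd) / nr \
        * (p.n_stem - ns) / p.n_stem
    ws_minus = (p.r1 * (1 - p.u1) * (p.n_stem - ns)
                + p.rt1 * p.eta1 * (p.n_diff - nd)) / nr * ns / p.n_stem
    wd_plus = (p.rt2 * (1 - p.eta2) * nd + p.r2 * p.u2 * ns) / nr \
        * (p.n_diff - nd) / p.n_diff
    wd_minus = (p.rt1 * (1 - p.eta1) * (p.n_diff - nd)
                + p.r1 * p.u1 * (p.n_stem - ns)) / nr * nd / p.n_diff

    w_none = 1.0 - (ws_plus + ws_minus + wd_plus + wd_minus)
    return TransitionProbabilities(ws_plus, ws_minus, wd_plus, wd_minus, w_none)


def is_absorbing(params: ModelParameters, state: PopulationState) -> bool:
    """True when all four move probabilities vanish at ``state``."""
    w = transition_probabilities(params, state)
    return w.ws_plus == w.ws_minus == w.wd_plus == w.wd_minus == 0.0


def extra_absorbing_states(params: ModelParameters) -> list[PopulationState]:
    """Absorbing states other than (0,0) and (N_S, N_D).

    Only the two mixed corners can qualify: (N_S, 0) is absorbing iff
    mutant SCs never differentiate (u2 = 0) and wild-type DCs never
    dedifferentiate (eta1 = 0); symmetrically for (0, N_D).  The corners
    are checked directly through the transition probabilities, which also
    covers edge cases with vanishing rates.
    """
    p = params
    out = []
    for corner in (
        PopulationState(p.n_stem, 0),
        PopulationState(0, p.n_diff),
    ):
        if is_absorbing(p, corner):
            out.append(corner)
    return out


def _check_state(params: ModelParameters, state: PopulationState) -> None:
    ns, nd = state
    if not (0 <= ns <= params.n_stem and 0 <= nd <= params.n_diff):
        raise ValueError(
            f"state {state} outside the grid "
            f"[0, {params.n_stem}] x [0, {params.n_diff}]"
        )
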