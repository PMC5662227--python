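"""Deterministic (infinite-population) replicator dynamics.

In the large-N limit the mutant frequencies x_S = <n_S>/N_S and
x_D = <n_D>/N_D obey

  dx_S/dt = { [r2(1-u2) - r1(1-u1)] x_S(1-x_S) + rt2 eta2 x_D(1-x_S)
              - rt1 eta1 x_S(1-x_D) } / phi
  dx_D/dt = { [rt2(1-eta2) - rt1(1-eta1)] x_D(1-x_D) + r2 u2 x_S(1-x_D)
              - r1 u1 x_D(1-x_S) } / phi

with the common positive denominator
phi = r1(1-x_S) + r2 x_S + rt1(1-x_D) + rt2 x_D.  The denominator rescales
time only: fixed points and stability signs are those of the numerator
field.  The leading eigenvalue of the Jacobian at the extinction state
(0, 0) decides mutant invasion; its zero locus is the transcritical phase
boundary studied in :mod:`stemoran.phase_diagram`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .model_core import ModelParameters, validate_parameters

__all__ = [
    "ReplicatorState",
    "FixedPoint",
    "Trajectory",
    "replicator_rhs",
    "integrate",
    "find_fixed_points",
    "origin_jacobian",
    "invasion_eigenvalue",
]

_EIG_TOL = 1e-9  # hyperbolicity threshold on eigenvalue real parts
_RESID_TOL = 1e-10


class ReplicatorState(NamedTuple):
    x_s: float
    x_d: float


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    x_s: np.ndarray
    x_d: np.ndarray
    converged: bool


@dataclass(frozen=True)
class FixedPoint:
    """Stationary point with Jacobian eigenvalues and stability class
    ('stable', 'unstable', 'saddle' or 'non-hyperbolic')."""

    location: ReplicatorState
    eigenvalues: tuple[complex, complex]
    stability: str


def _numerators(p: ModelParameters, xs: float, xd: float) -> tuple[float, float]:
    a = p.r2 * (1 - p.u2) - p.r1 * (1 - p.u1)
    fs = a * xs * (1 - xs) + p.rt2 * p.eta2 * xd * (1 - xs) \
        - p.rt1 * p.eta1 * xs * (1 - xd)
    d = p.rt2 * (1 - p.eta2) - p.rt1 * (1 - p.eta1)
    fd = d * xd * (1 - xd) + p.r2 * p.u2 * xs * (1 - xd) \
        - p.r1 * p.u1 * xd * (1 - xs)
    return fs, fd


def _denominator(p: ModelParameters, xs: float, xd: float) -> float:
    return p.r1 * (1 - xs) + p.r2 * xs + p.rt1 * (1 - xd) + p.rt2 * xd


def _numerator_jacobian(p: ModelParameters, xs: float, xd: float) -> np.ndarray:
    a = p.r2 * (1 - p.u2) - p.r1 * (1 - p.u1)
    b = p.rt2 * p.eta2
    c = p.rt1 * p.eta1
    d = p.rt2 * (1 - p.eta2) - p.rt1 * (1 - p.eta1)
    e = p.r2 * p.u2
    g = p.r1 * p.u1
    return np.array([
        [a * (1 - 2 * xs) - b * xd - c * (1 - xd), b * (1 - xs) + c * xs],
        [e * (1 - xd) + g * xd, d * (1 - 2 * xd) - e * xs - g * (1 - xs)],
    ])


def replicator_rhs(
    params: ModelParameters, state: ReplicatorState
) -> tuple[float, float]:
    """(dx_S/dt, dx_D/dt) at ``state``."""
    p = params
    xs, xd = state
    if not (0.0 <= xs <= 1.0 and 0.0 <= xd <= 1.0):
        raise ValueError(f"state {state} outside the unit square")
    phi = _denominator(p, xs, xd)
    if phi <= 0.0:
        raise ValueError("replicator denominator vanishes (all rates zero)")
    fs, fd = _numerators(p, xs, xd)
    return (fs / phi, fd / phi)


def integrate(
    params: ModelParameters,
    initial: ReplicatorState,
    t_end: float,
    tol: float = 1e-8,
) -> Trajectory:
    """Integrate the flow to ``t_end``, stopping early once the velocity
    norm drops below ``tol`` (converged).  Sub-tolerance overshoots of the
    unit square are projected back."""
    p = validate_parameters(params)
    xs0, xd0 = initial
    if not (0.0 <= xs0 <= 1.0 and 0.0 <= xd0 <= 1.0):
        raise ValueError(f"initial state {initial} outside the unit square")

    def rhs(_t, y):
        x = float(np.clip(y[0], 0.0, 1.0))
        z = float(np.clip(y[1], 0.0, 1.0))
        phi = _denominator(p, x, z)
        fs, fd = _numerators(p, x, z)
        return [fs / phi, fd / phi]

    def settled(_t, y):
        v = rhs(_t, y)
        return float(np.hypot(*v)) - tol

    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(
        rhs, (0.0, t_end), [xs0, xd0], method="RK45",
        rtol=1e-8, atol=1e-10, events=settled, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    xs = np.clip(sol.y[0], 0.0, 1.0)
    xd = np.clip(sol.y[1], 0.0, 1.0)
    converged = bool(sol.t_events[0].size) or bool(
        np.hypot(*rhs(sol.t[-1], [xs[-1], xd[-1]])) < tol
    )
    return Trajectory(sol.t, xs, xd, converged)


def _classify(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) <= _EIG_TOL):
        return "non-hyperbolic"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(
    params: ModelParameters, grid: int = 16, dedup: float = 1e-8
) -> list[FixedPoint]:
    """All stationary states in the closed unit square.

    Multi-start Newton search on the numerator field from a ``grid`` x
    ``grid`` lattice, the four corners always checked explicitly;
    duplicates within ``dedup`` are merged.  Stability comes from the
    eigenvalues of the numerator Jacobian scaled by the (positive) local
    denominator.
    """
    p = validate_parameters(params)
    found: list[tuple[float, float]] = []

    def consider(xs: float, xd: float):
        if not (-1e-9 <= xs <= 1 + 1e-9 and -1e-9 <= xd <= 1 + 1e-9):
            return
        xs = float(np.clip(xs, 0.0, 1.0))
        xd = float(np.clip(xd, 0.0, 1.0))
        fs, fd = _numerators(p, xs, xd)
        if abs(fs) > _RESID_TOL or abs(fd) > _RESID_TOL:
            return
        for ys, yd in found:
            if (xs - ys) ** 2 + (xd - yd) ** 2 < dedup**2:
                return
        found.append((xs, xd))

    for corner in ((0.0, 0.0), (1.0, 1.0), (1.0, 0.0), (0.0, 1.0)):
        consider(*corner)
    pts = np.linspace(0.0, 1.0, grid)
    for xs0 in pts:
        for xd0 in pts:
            sol = _scipy_root(
                lambda v: _numerators(p, v[0], v[1]), [xs0, xd0],
                jac=lambda v: _numerator_jacobian(p, v[0], v[1]),
                method="hybr", tol=1e-13,
            )
            if sol.success:
                consider(sol.x[0], sol.x[1])

    out = []
    for xs, xd in sorted(found):
        jac = _numerator_jacobian(p, xs, xd) / _denominator(p, xs, xd)
        eigs = np.linalg.eigvals(jac)
        out.append(
            FixedPoint(
                ReplicatorState(xs, xd),
                (complex(eigs[0]), complex(eigs[1])),
                _classify(eigs),
            )
        )
    return out


def origin_jacobian(params: ModelParameters) -> np.ndarray:
    """Jacobian of the numerator field at the extinction state (0, 0):
    [[r2(1-u2) - r1(1-u1) - rt1 eta1, rt2 eta2],
     [r2 u2, rt2(1-eta2) - rt1(1-eta1) - r1 u1]]."""
    return _numerator_jacobian(params, 0.0, 0.0)


def invasion_eigenvalue(params: ModelParameters) -> float:
    """Leading eigenvalue of the origin Jacobian divided by the origin
    denominator r1 + rt1.

    Positive means a rare mutant invades (advantaged), negative that it is
    purged; only the sign carries meaning, the denominator fixes the time
    scale.  Off-diagonal entries are non-negative, so the leading
    eigenvalue is real.
    """
    p = validate_parameters(params)
    jac = origin_jacobian(p) / (p.r1 + p.rt1)
    eigs = np.linalg.eigvals(jac)
    return float(np.max(np.real(eigs)))
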