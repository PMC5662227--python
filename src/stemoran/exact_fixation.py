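"""Fixation probabilities from the generating-function (martingale) method.

For the four-compartment Moran chain one can seek a pair of auxiliary
constants ``(z_s, z_d)`` such that ``z_s**n_s * z_d**n_d`` is (approximately)
a martingale of the process.  The stationarity condition yields a coupled
pair of algebraic equations,

    (z_s - 1) [r2 (1-u2) z_s - r1 (1-u1) - rt1 eta1] + (z_d - 1) z_s r2 u2 = 0
    (z_d - 1) [rt2 (1-eta2) z_d - rt1 (1-eta1) - r1 u1] + (z_s - 1) z_d rt2 eta2 = 0

whose non-trivial solution gives the fixation probability starting from
``i`` mutant stem cells and ``j`` mutant non-stem cells as

    rho_ij = (1 - z_s**i z_d**j) / (1 - z_s**N_S z_d**N_D).

The system always admits the trivial root (1, 1); the solver enumerates all
real branches by polynomial elimination and selects the admissible
non-trivial one.  Because the total fitness N_r is frequency dependent, the
martingale property is not exact for strongly coupled regimes (large
differentiation u2 combined with dedifferentiation); compare against
:mod:`stemoran.markov_oracle` for the exact finite-chain answer.

Closed-form special cases (decoupled compartments, negligible DC division,
strict hierarchy without plasticity) are provided separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParameters, ParameterError, validate_parameters

__all__ = [
    "RootSolveError",
    "AuxiliaryRoots",
    "FixationResult",
    "solve_auxiliary_roots",
    "fixation_from_counts",
    "fixation_summary",
    "closed_form_decoupled",
    "closed_form_negligible_dc",
    "closed_form_hierarchical",
    "success_by_time",
]

_RESIDUAL_TOL = 1e-10
_DEGENERATE_TOL = 1e-6
_CLIP_SLACK = 1e-12


class RootSolveError(RuntimeError):
    """No admissible auxiliary root could be selected."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates or [])


@dataclass(frozen=True)
class AuxiliaryRoots:
    """Selected non-trivial solution of the auxiliary-root system.

    ``is_degenerate`` flags the transcritical (neutrality) case where the
    non-trivial branch passes through (1, 1) and the fixation formula
    becomes 0/0; downstream evaluation then uses a symmetric epsilon
    perturbation of the mutant rates.  ``residuals`` are the two equation
    residuals at the returned pair.
    """

    z_s: float
    z_d: float
    is_degenerate: bool
    residuals: tuple[float, float]


@dataclass(frozen=True)
class FixationResult:
    """Fixation probabilities for the three canonical initial conditions.

    rho_s: single initial mutant stem cell, state (1, 0).
    rho_d: single initial mutant non-stem cell, state (0, 1).
    rho_avg: a single mutant placed uniformly at random in the population,
        i.e. (N_S rho_s + N_D rho_d) / N_tot.
    """

    rho_s: float
    rho_d: float
    rho_avg: float
    n_tot: int


# ---------------------------------------------------------------------------
# root system


def _system_residuals(p: ModelParameters, zs: float, zd: float) -> tuple[float, float]:
    f1 = (zs - 1.0) * (p.r2 * (1 - p.u2) * zs - p.r1 * (1 - p.u1) - p.rt1 * p.eta1) \
        + (zd - 1.0) * zs * p.r2 * p.u2
    f2 = (zd - 1.0) * (p.rt2 * (1 - p.eta2) * zd - p.rt1 * (1 - p.eta1) - p.r1 * p.u1) \
        + (zs - 1.0) * zd * p.rt2 * p.eta2
    return (f1, f2)


def _real_root_candidates(p: ModelParameters) -> list[tuple[float, float]]:
    """All real solution pairs of the coupled system, trivial root included.

    The first equation is linear in z_d given z_s; eliminating z_d and
    clearing denominators leaves a quartic in z_s whose real roots are
    back-substituted.  When r2*u2 = 0 the first equation factorizes instead
    and z_d follows from the (then quadratic) second equation.
    """
    A = p.r2 * (1 - p.u2)
    B = p.r1 * (1 - p.u1) + p.rt1 * p.eta1
    C = p.r2 * p.u2
    D = p.rt2 * (1 - p.eta2)
    E = p.rt1 * (1 - p.eta1) + p.r1 * p.u1
    F = p.rt2 * p.eta2

    cands: list[tuple[float, float]] = []

    if C > 0.0:
        # g(z) := -(z-1)(A z - B) = C z (z_d - 1); substituting into the
        # second equation and multiplying by (C z)^2 gives the quartic
        #   g [D (C z + g) - E C z] + (z - 1)(C z + g) F C z = 0
        g = np.array([-A, A + B, -B])
        cz = np.array([C, 0.0])
        term1 = np.polymul(
            g, np.polyadd(D * np.polyadd(cz, g), -E * cz)
        )
        term2 = np.polymul(
            np.polymul([1.0, -1.0], np.polyadd(cz, g)), F * cz
        )
        poly = np.polyadd(term1, term2)
        poly = np.trim_zeros(poly, "f")
        if poly.size > 1:
            for z in np.roots(poly):
                if abs(z.imag) < 1e-9 and abs(z.real) > 1e-12:
                    zs = float(z.real)
                    zd = 1.0 - (zs - 1.0) * (A * zs - B) / (C * zs)
                    cands.append((zs, zd))
    else:
        # first equation factorizes: z_s = 1 or A z_s = B
        zs_options = [1.0]
        if A > 0.0:
            zs_options.append(B / A)
        for zs in zs_options:
            # D z_d^2 + (-(D + E) + (z_s - 1) F) z_d + E = 0
            coeffs = np.array([D, -(D + E) + (zs - 1.0) * F, E])
            coeffs = np.trim_zeros(coeffs, "f")
            if coeffs.size <= 1:
                continue
            for zd in np.roots(coeffs):
                if abs(np.imag(zd)) < 1e-9:
                    cands.append((float(zs), float(np.real(zd))))
    return cands


def _rho(zs: float, zd: float, i: int, j: int, ns: int, nd: int) -> float:
    den = 1.0 - zs**ns * zd**nd
    return (1.0 - zs**i * zd**j) / den


def _is_trivial(zs: float, zd: float, tol: float = _DEGENERATE_TOL) -> bool:
    return abs(zs - 1.0) < tol and abs(zd - 1.0) < tol


def _admissible(p: ModelParameters, zs: float, zd: float) -> bool:
    if _is_trivial(zs, zd) or zs <= 0.0 or zd <= 0.0:
        return False
    den = 1.0 - zs**p.n_stem * zd**p.n_diff
    if abs(den) < 1e-12:
        return False
    lo, hi = -1e-9, 1.0 + 1e-9
    for i, j in ((1, 0), (0, 1)):
        r = _rho(zs, zd, i, j, p.n_stem, p.n_diff)
        if not (lo <= r <= hi):
            return False
    f1, f2 = _system_residuals(p, zs, zd)
    return abs(f1) <= 1e-8 and abs(f2) <= 1e-8


def _homotopy_root(p: ModelParameters, n_steps: int = 16):
    """Continue the root from the decoupled limit (u = eta = 0) to ``p``.

    At s = 0 the system factorizes with root (r1/r2, rt1/rt2); the
    differentiation and plasticity probabilities are scaled up linearly and
    at every step the candidate nearest to the previous root is kept.  This
    is the principled branch tie-break: the martingale root must connect
    continuously to the classical Moran limit.
    """
    if p.r2 <= 0.0 or p.rt2 <= 0.0:
        return None
    prev = (p.r1 / p.r2, p.rt1 / p.rt2)
    for k in range(1, n_steps + 1):
        s = k / n_steps
        ps = p.replace(u1=s * p.u1, u2=s * p.u2, eta1=s * p.eta1, eta2=s * p.eta2)
        cands = _real_root_candidates(ps)
        adm = [(zs, zd) for zs, zd in cands if _admissible(ps, zs, zd)]
        if not adm:
            return None
        prev = min(adm, key=lambda c: (c[0] - prev[0]) ** 2 + (c[1] - prev[1]) ** 2)
    return prev


def solve_auxiliary_roots(params: ModelParameters) -> AuxiliaryRoots:
    """Solve the coupled auxiliary-root system and select the branch.

    Returns the non-trivial real pair ``(z_s, z_d)``; at a transcritical /
    neutrality point, where the non-trivial branch collides with the
    trivial root (1, 1), a degenerate result is returned and fixation
    values are later obtained as the limit along an epsilon perturbation.

    Raises :class:`RootSolveError` when no admissible branch exists (all
    real candidate pairs are attached for diagnosis).
    """
    p = validate_parameters(params)
    cands = _real_root_candidates(p)
    adm = [(zs, zd) for zs, zd in cands if _admissible(p, zs, zd)]

    if len(adm) == 1:
        zs, zd = adm[0]
    elif len(adm) > 1:
        picked = _homotopy_root(p)
        if picked is None:
            raise RootSolveError(
                "multiple admissible roots and homotopy tie-break failed",
                cands,
            )
        zs, zd = picked
    else:
        # no admissible candidate: transcritical point if the non-trivial
        # branch has collapsed onto (1, 1) — probe by perturbing the mutant
        # rates both ways and checking the perturbed branches approach (1,1)
        if _degenerate_probe(p):
            return AuxiliaryRoots(1.0, 1.0, True, _system_residuals(p, 1.0, 1.0))
        raise RootSolveError(
            f"no admissible auxiliary root for {p}; real candidates: {cands}",
            cands,
        )

    if _is_trivial(zs, zd):
        return AuxiliaryRoots(1.0, 1.0, True, _system_residuals(p, 1.0, 1.0))
    f1, f2 = _system_residuals(p, zs, zd)
    if abs(f1) > _RESIDUAL_TOL or abs(f2) > _RESIDUAL_TOL:
        # polish with one Newton step pair via scipy if plain back-substitution
        # left residual above tolerance
        from scipy.optimize import fsolve

        sol = fsolve(lambda v: _system_residuals(p, v[0], v[1]), [zs, zd],
                     full_output=False, xtol=1e-13)
        zs, zd = float(sol[0]), float(sol[1])
        f1, f2 = _system_residuals(p, zs, zd)
    return AuxiliaryRoots(zs, zd, False, (f1, f2))


def _degenerate_probe(p: ModelParameters, eps: float = 1e-4) -> bool:
    for sign in (+1.0, -1.0):
        q = p.replace(r2=p.r2 * (1 + sign * eps), rt2=p.rt2 * (1 + sign * eps))
        cands = _real_root_candidates(q)
        adm = [(zs, zd) for zs, zd in cands if _admissible(q, zs, zd)]
        if len(adm) != 1:
            return False
        zs, zd = adm[0]
        if abs(zs - 1.0) > 0.05 or abs(zd - 1.0) > 0.05:
            return False
    return True


# ---------------------------------------------------------------------------
# fixation formulas


def fixation_from_counts(
    params: ModelParameters, roots: AuxiliaryRoots, i: int, j: int
) -> float:
    """rho_ij = (1 - z_s^i z_d^j) / (1 - z_s^N_S z_d^N_D).

    In the degenerate (neutral) case the analytic limit is taken along a
    symmetric relative perturbation of the mutant rates.
    """
    p = params
    if not (0 <= i <= p.n_stem and 0 <= j <= p.n_diff):
        raise ValueError(f"initial counts ({i}, {j}) outside the state grid")
    if roots.is_degenerate:
        return _degenerate_rho(p, i, j)
    den = 1.0 - roots.z_s**p.n_stem * roots.z_d**p.n_diff
    if abs(den) < 1e-12:
        raise RootSolveError(
            "fixation denominator vanishes for a non-degenerate root "
            "(wrong branch selected)"
        )
    rho = (1.0 - roots.z_s**i * roots.z_d**j) / den
    return _clip_probability(rho)


def _degenerate_rho(p: ModelParameters, i: int, j: int, eps: float = 1e-6) -> float:
    vals = []
    for sign in (+1.0, -1.0):
        q = p.replace(r2=p.r2 * (1 + sign * eps), rt2=p.rt2 * (1 + sign * eps))
        r = solve_auxiliary_roots(q)
        if r.is_degenerate:
            raise RootSolveError("perturbed system still degenerate")
        vals.append(fixation_from_counts(q, r, i, j))
    return 0.5 * (vals[0] + vals[1])


def _clip_probability(x: float) -> float:
    if -_CLIP_SLACK <= x < 0.0:
        return 0.0
    if 1.0 < x <= 1.0 + _CLIP_SLACK:
        return 1.0
    if not (0.0 <= x <= 1.0):
        raise RootSolveError(f"fixation probability {x} outside [0, 1]")
    return x


def fixation_summary(
    params: ModelParameters, roots: AuxiliaryRoots | None = None
) -> FixationResult:
    """rho_S, rho_D and the uniformly averaged rho for ``params``.

    In the fully decoupled case (u = eta = 0) the two compartments are
    independent Moran processes and "fixation" is read per niche: rho_S
    (rho_D) is the probability that a single mutant dominates its own
    compartment, the classical (1 - x)/(1 - x^N) formula.
    """
    p = params
    if p.u1 == p.u2 == p.eta1 == p.eta2 == 0.0:
        rho_s, rho_d = closed_form_decoupled(p)
        return FixationResult(
            rho_s, rho_d,
            (p.n_stem * rho_s + p.n_diff * rho_d) / p.n_tot,
            p.n_tot,
        )
    if roots is None:
        roots = solve_auxiliary_roots(p)
    rho_s = fixation_from_counts(p, roots, 1, 0)
    rho_d = fixation_from_counts(p, roots, 0, 1)
    if roots.is_degenerate:
        rho_avg = (p.n_stem * rho_s + p.n_diff * rho_d) / p.n_tot
    else:
        den = 1.0 - roots.z_s**p.n_stem * roots.z_d**p.n_diff
        rho_avg = _clip_probability(
            (1.0 - (p.n_stem / p.n_tot) * roots.z_s
             - (p.n_diff / p.n_tot) * roots.z_d) / den
        )
    return FixationResult(rho_s, rho_d, rho_avg, p.n_tot)


# ---------------------------------------------------------------------------
# closed-form special cases


def _moran_rho(ratio: float, n: int) -> float:
    """Classical Moran fixation (1 - x)/(1 - x^n) with the neutral limit 1/n."""
    if abs(ratio - 1.0) < 1e-9:
        return 1.0 / n
    if ratio == 0.0:
        return 1.0
    return (1.0 - ratio) / (1.0 - ratio**n)


def closed_form_decoupled(params: ModelParameters) -> tuple[float, float]:
    """Fixation in each compartment when u = eta = 0 (two disjoint Moran
    processes): rho_1 for the SC niche, rho_2 for the DC compartment."""
    p = params
    if p.u1 or p.u2 or p.eta1 or p.eta2:
        raise ParameterError("decoupled closed form requires u = eta = 0")
    if p.r2 <= 0.0 or p.rt2 <= 0.0:
        raise ParameterError("mutant rates must be positive")
    return (
        _moran_rho(p.r1 / p.r2, p.n_stem),
        _moran_rho(p.rt1 / p.rt2, p.n_diff),
    )


def closed_form_negligible_dc(params: ModelParameters) -> float:
    """Average fixation when non-stem cells effectively do not divide
    (rt1 = rt2 = 0): only SC-born mutants can fix, so
    rho = N_S/N_tot * (1 - r1/r2)/(1 - (r1/r2)^N_S)."""
    p = params
    if p.rt1 != 0.0 or p.rt2 != 0.0:
        raise ParameterError("negligible-DC closed form requires rt1 = rt2 = 0")
    if p.r2 <= 0.0:
        raise ParameterError("r2 must be positive")
    return p.n_stem / p.n_tot * _moran_rho(p.r1 / p.r2, p.n_stem)


def closed_form_hierarchical(params: ModelParameters) -> float:
    """rho_S in the strict hierarchy (eta1 = eta2 = 0, u2 > 0).

    Without dedifferentiation the SC niche is an autonomous Moran process
    with constant success ratio z = r1 (1-u1) / (r2 (1-u2)); DC-born mutants
    never fix (rho_D = 0).  This reduction is exact for the finite chain.
    """
    p = params
    if p.eta1 != 0.0 or p.eta2 != 0.0:
        raise ParameterError("hierarchical closed form requires eta1 = eta2 = 0")
    if p.u2 <= 0.0:
        raise ParameterError(
            "hierarchical closed form requires u2 > 0 so DC fixation follows"
        )
    denom = p.r2 * (1 - p.u2)
    if denom == 0.0:
        raise ParameterError("effective mutant SC rate r2 (1-u2) vanishes")
    z = p.r1 * (1 - p.u1) / denom
    return _moran_rho(z, p.n_stem)


def success_by_time(params: ModelParameters, mu: float, t: float) -> float:
    """Probability that a successful mutant has emerged before time ``t``
    under mutation rate ``mu`` per cell per unit time:
    P(t) = 1 - exp(-N_tot * mu * rho_avg * t)."""
    if mu < 0 or t < 0:
        raise ValueError("mu and t must be non-negative")
    rho = fixation_summary(params).rho_avg
    return -math.expm1(-params.n_tot * mu * rho * t)
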