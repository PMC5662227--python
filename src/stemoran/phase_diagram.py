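"""Neutrality boundaries between advantaged and disadvantaged mutants.

Three routes to the same transcritical locus:

* a closed-form quadratic in the relative fitness r for the symmetric
  parameterization (r1 = rt1 = 1, r2 = rt2 = r, u1 = u2 = u, eta1 = 0,
  eta2 = eta):  (u + eta - 1) r^2 + [-u^2 + (eta-1) u + 2 - eta] r
  - 1 + u^2 = 0;
* generic root finding on the invasion eigenvalue (works for arbitrary
  alpha, beta, epsilon, eta1);
* the finite-population counterpart, the crossing of rho_S = 1/N_S
  computed from the generating-function solver.

The quadratic can have two positive roots; only the one where the origin
Jacobian has negative trace is a genuine stability change (at the other an
eigenvalue is already positive), so that root is always selected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import exact_fixation, replicator
from .model_core import ModelParameters

__all__ = [
    "SweepParameterization",
    "PhaseBoundary",
    "boundary_r_closed_form",
    "boundary_numeric",
    "boundary_finite_population",
    "sweep",
]

_BRACKET_TOL = 1e-10


@dataclass(frozen=True)
class SweepParameterization:
    """Reduced parameterization used for figures and boundary hunts.

    Mutant rates are r2 = alpha*r and rt2 = beta*r against wild-type rates
    fixed at 1; differentiation is u1 = u, u2 = eps*u (eps = 1 unless
    given); dedifferentiation is eta2 = eta with eta1 free (default 0,
    mutant-only plasticity).
    """

    r: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    u: float = 0.0
    eps: float | None = None
    eta: float = 0.0
    eta1: float = 0.0

    def to_parameters(self, n_stem: int = 10, n_diff: int = 10) -> ModelParameters:
        eps = 1.0 if self.eps is None else self.eps
        return ModelParameters(
            n_stem=n_stem,
            n_diff=n_diff,
            r1=1.0,
            r2=self.alpha * self.r,
            rt1=1.0,
            rt2=self.beta * self.r,
            u1=self.u,
            u2=eps * self.u,
            eta1=self.eta1,
            eta2=self.eta,
        )

    def with_axis(self, axis: str, value: float) -> "SweepParameterization":
        return replace(self, **{axis: value})


@dataclass(frozen=True)
class PhaseBoundary:
    """A boundary locus: critical values of one varied parameter with the
    frozen coordinates and defining residual at each point."""

    axis: str
    method: str  # closed_form | eigenvalue | finite_population
    points: tuple[dict, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.points))


def _origin_trace_symmetric(r: float, u: float, eta: float) -> float:
    # trace of the origin Jacobian in the symmetric parameterization
    return (r * (1 - u) - (1 - u)) + (r * (1 - eta) - 1 - u)


def boundary_r_closed_form(u: float, eta: float) -> float:
    """Critical relative fitness r* from the boundary quadratic.

    Among real positive roots the one with negative origin-Jacobian trace
    is returned — the genuine transcritical point.  The degenerate linear
    case u + eta = 1 and the double root at u = eta = 0 (r* = 1) are
    handled explicitly.
    """
    if not (0.0 <= u <= 1.0 and 0.0 <= eta <= 1.0):
        raise ValueError("u and eta must lie in [0, 1]")
    a = u + eta - 1.0
    b = -u * u + (eta - 1.0) * u + 2.0 - eta
    c = u * u - 1.0
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            raise ValueError("boundary polynomial vanishes identically")
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            raise ValueError(f"no real boundary root for u={u}, eta={eta}")
        sq = np.sqrt(disc)
        roots = [(-b + sq) / (2 * a), (-b - sq) / (2 * a)]
    positive = sorted(r for r in roots if r > 0.0)
    if not positive:
        raise ValueError(f"no positive boundary root for u={u}, eta={eta}")
    if len(positive) == 1:
        return positive[0]
    admissible = [r for r in positive if _origin_trace_symmetric(r, u, eta) < 1e-12]
    if not admissible:
        raise ValueError(
            f"no admissible (negative-trace) boundary root among {positive}"
        )
    return admissible[0]


def boundary_numeric(
    template: SweepParameterization,
    bracket: tuple[float, float],
    axis: str = "r",
    n_stem: int = 10,
    n_diff: int = 10,
) -> float:
    """Critical value of ``axis`` where the invasion eigenvalue changes sign."""

    def f(v: float) -> float:
        params = template.with_axis(axis, v).to_parameters(n_stem, n_diff)
        return replicator.invasion_eigenvalue(params)

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ValueError(
            f"invasion eigenvalue does not change sign on [{lo}, {hi}] "
            f"({flo:+.3g} .. {fhi:+.3g})"
        )
    return float(brentq(f, lo, hi, xtol=_BRACKET_TOL))


def boundary_finite_population(
    template: SweepParameterization,
    params_base: ModelParameters,
    bracket: tuple[float, float],
    axis: str = "r",
    use_average: bool = False,
) -> float:
    """Finite-N neutrality: the crossing of rho_S = 1/N_S (or, with
    ``use_average``, rho_avg = 1/N_tot) along ``axis``."""
    ns, nd = params_base.n_stem, params_base.n_diff
    target = 1.0 / (ns + nd) if use_average else 1.0 / ns

    def f(v: float) -> float:
        params = template.with_axis(axis, v).to_parameters(ns, nd)
        res = exact_fixation.fixation_summary(params)
        rho = res.rho_avg if use_average else res.rho_s
        return rho - target

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"rho - 1/N does not change sign on [{lo}, {hi}] "
            f"({flo:+.3g} .. {fhi:+.3g})"
        )
    return float(brentq(f, lo, hi, xtol=_BRACKET_TOL))


def sweep(
    template: SweepParameterization,
    grid: dict[str, "list[float] | np.ndarray"],
    n_stem: int = 10,
    n_diff: int = 10,
    finite_classification: bool = False,
) -> pd.DataFrame:
    """Evaluate fixation probabilities and the invasion eigenvalue over a
    parameter grid.

    ``grid`` maps SweepParameterization field names to value lists; the
    cartesian product is evaluated in deterministic (row-major) order.
    Per-row solver failures are recorded in the ``error`` column rather
    than aborting the sweep.  The ``advantaged`` flag uses the sign of the
    invasion eigenvalue by default, or rho_S > 1/N_S with
    ``finite_classification``.
    """
    axes = list(grid.keys())
    rows = []
    for combo in itertools.product(*(grid[a] for a in axes)):
        t = template
        for a, v in zip(axes, combo):
            t = t.with_axis(a, float(v))
        params = t.to_parameters(n_stem, n_diff)
        row = {
            "r": t.r, "alpha": t.alpha, "beta": t.beta, "u": t.u,
            "eps": 1.0 if t.eps is None else t.eps,
            "eta": t.eta, "eta1": t.eta1,
            "u1": params.u1, "u2": params.u2,
            "rho_s": np.nan, "rho_d": np.nan, "rho_avg": np.nan,
            "eigenvalue": np.nan, "advantaged": None, "error": "",
        }
        try:
            res = exact_fixation.fixation_summary(params)
            eig = replicator.invasion_eigenvalue(params)
            row.update(
                rho_s=res.rho_s, rho_d=res.rho_d, rho_avg=res.rho_avg,
                eigenvalue=eig,
            )
            row["advantaged"] = bool(
                res.rho_s > 1.0 / n_stem if finite_classification else eig > 0
            )
        except Exception as exc:  # per-row failure is data, not fatal
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
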