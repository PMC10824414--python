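"""Two-compartment dynamics of HSC (S) and progenitor (P) numbers.

With p(t), q(t), pp(t) the fractions of S-S, S-P and P-P divisions and r the
HSC division rate (per week),

    dS/dt = r p(t) S - r pp(t) S          = r (p - pp) S
    dP/dt = r q(t) S + 2 r pp(t) S - d P

where d lumps progenitor differentiation out of the KSL gate.  HSC death is
omitted (apoptotic fractions in the HSC gate are negligible at all measured
ages).  The observable KSL compartment is S + P.

Two solution routes are provided and cross-validated:

* :func:`integrate_model` — adaptive Runge-Kutta (rtol 1e-8 / atol 1e-10),
  the general-purpose solver;
* :func:`model_counts` / :class:`FractionSchedule` — the semi-analytic exact
  solution of this linear system (S by exponential of a quadrature, P by an
  integrating factor), evaluated on a fine fixed grid.  This route costs
  microseconds per parameter set and backs the inference loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .division_fractions import DivisionThresholds, division_fractions_at
from .errors import DomainError, IntegrationError, ValidationError
from .shape_dynamics import ShapeTrajectory

_RTOL = 1e-8
_ATOL = 1e-10
#: Default step (weeks) of the semi-analytic quadrature grid.
GRID_STEP_WEEKS = 0.02


@dataclass(frozen=True)
class ModelParams:
    """ODE parameters: division rate r, progenitor removal rate d (both per
    week) and the compartment sizes at the trajectory origin t0."""

    r: float
    d: float
    S0: float
    P0: float
    t0: float = 4.0

    def __post_init__(self) -> None:
        for name in ("r", "d", "S0", "P0"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"parameter {name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class PopulationTrajectory:
    """Solution sampled on an age grid; KSL = S + P."""

    ages: np.ndarray
    S: np.ndarray
    P: np.ndarray

    @property
    def KSL(self) -> np.ndarray:
        return self.S + self.P


def _as_pqpp(fr) -> tuple[float, float, float]:
    if hasattr(fr, "p"):
        return fr.p, fr.q, fr.pp
    p, q, pp = fr
    return p, q, pp


def integrate_model(
    params: ModelParams,
    fractions: Callable[[float], object],
    ages: Sequence[float],
) -> PopulationTrajectory:
    """Solve the ODE system on ``ages`` with an adaptive RK solver.

    ``fractions`` maps an age (weeks) to the division fractions at that age,
    either a :class:`DivisionFractions` or a plain (p, q, pp) triple.
    ``ages[0]`` must equal ``params.t0``.
    """
    ages = np.asarray(ages, dtype=float)
    if abs(ages[0] - params.t0) > 1e-12:
        raise DomainError(f"ages[0]={ages[0]} must equal t0={params.t0}")
    if np.any(np.diff(ages) <= 0):
        raise DomainError("ages must be strictly increasing")
    r, d = params.r, params.d

    def rhs(t, y):
        p, q, pp = _as_pqpp(fractions(t))
        return [r * (p - pp) * y[0], r * (q + 2.0 * pp) * y[0] - d * y[1]]

    sol = solve_ivp(
        rhs, (ages[0], ages[-1]), [params.S0, params.P0],
        t_eval=ages, rtol=_RTOL, atol=_ATOL, method="RK45", dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed near age {sol.t[-1] if len(sol.t) else ages[0]}: {sol.message}")
    return PopulationTrajectory(ages=ages, S=sol.y[0], P=sol.y[1])


def steady_growth_rate(params: ModelParams, fractions, t: float) -> float:
    """Instantaneous net HSC growth rate r (p(t) - pp(t)); zero when
    self-renewal and symmetric differentiation balance."""
    p, _q, pp = _as_pqpp(fractions(t) if callable(fractions) else fractions)
    return params.r * (p - pp)


class FractionSchedule:
    """Precomputed division-fraction arrays on a fine age grid.

    Caches g = p - pp (net self-renewal excess) and h = q + 2 pp (progenitor
    source coefficient) with the running integral of g, so that the exact
    linear-ODE solution can be evaluated for many (r, S0, P0) at negligible
    cost.
    """

    def __init__(
        self,
        traj: ShapeTrajectory,
        thr: DivisionThresholds,
        t0: float,
        t_max: float,
        step: float = GRID_STEP_WEEKS,
    ):
        if t0 < traj.t0 - 1e-12:
            raise DomainError(f"t0={t0} precedes trajectory origin {traj.t0}")
        n = max(int(np.ceil((t_max - t0) / step)), 2)
        self.ts = np.linspace(t0, t_max, n + 1)
        fr = [division_fractions_at(traj, float(t), thr) for t in self.ts]
        p = np.array([f.p for f in fr])
        q = np.array([f.q for f in fr])
        pp = np.array([f.pp for f in fr])
        self.t0 = t0
        self.g = p - pp
        self.h = q + 2.0 * pp
        self.G = cumulative_trapezoid(self.g, self.ts, initial=0.0)

    def counts(self, r: float, d: float, S0: float, P0: float, ages) -> tuple[np.ndarray, np.ndarray]:
        """Exact (S, KSL) at ``ages`` for the given parameters."""
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.t0 - 1e-9) or np.any(ages > self.ts[-1] + 1e-9):
            raise DomainError(f"ages must lie within [{self.t0}, {self.ts[-1]}]")
        u = self.ts - self.t0
        S_grid = S0 * np.exp(r * self.G)
        integrand = np.exp(d * u) * self.h * S_grid
        C = cumulative_trapezoid(integrand, self.ts, initial=0.0)
        S = S0 * np.exp(r * np.interp(ages, self.ts, self.G))
        P = np.exp(-d * (ages - self.t0)) * (P0 + r * np.interp(ages, self.ts, C))
        return S, S + P


def model_counts(
    params: ModelParams,
    traj: ShapeTrajectory,
    thr: DivisionThresholds,
    ages,
    step: float = GRID_STEP_WEEKS,
) -> tuple[np.ndarray, np.ndarray]:
    """Semi-analytic (S, KSL) at ``ages``; the forward model used by both the
    census generator and the inference objective."""
    ages = np.asarray(ages, dtype=float)
    sched = FractionSchedule(traj, thr, params.t0, max(float(ages.max()), params.t0 + 1.0), step)
    return sched.counts(params.r, params.d, params.S0, params.P0, ages)
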