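"""Biexponential age trajectories of the beta shape parameters.

The per-age MLE shape pairs (alpha_t, beta_t) are interpolated over age by

    alpha(t) = b1a * exp(-a1a * (t - t0)) + b2a * exp(-a2a * (t - t0))
    beta(t)  = b1b * exp(-a1b * (t - t0)) + b2b * exp(-a2b * (t - t0))

with t0 the first measured age (4 weeks in the reference design).  Each
curve has four free parameters fitted independently by unweighted nonlinear
least squares on the natural scale, from 20 deterministic multi-starts over
log-spaced rate pairs.  Rates may be negative (growth) — only positivity of
the evaluated curves over [t0, 72] is required, and violations warn.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .beta_estimation import AgeShapeEstimate
from .errors import DomainError, OptimizationError, ValidationError

logger = logging.getLogger(__name__)

_POSITIVITY_SPAN = (None, 72.0)  # checked from t0 to 72 weeks


@dataclass(frozen=True)
class ShapeTrajectory:
    """Biexponential parameter set for alpha(t) and beta(t).

    Within each curve, parameters are stored with the ordering convention
    a1 >= a2 (fast component first).
    """

    t0: float
    b1_alpha: float
    a1_alpha: float
    b2_alpha: float
    a2_alpha: float
    b1_beta: float
    a1_beta: float
    b2_beta: float
    a2_beta: float

    def __post_init__(self) -> None:
        ts = np.linspace(self.t0, _POSITIVITY_SPAN[1], 273)
        a, b = self.shapes(ts)
        if np.any(a <= 0) or np.any(b <= 0):
            logger.warning(
                "trajectory evaluates non-positive on [%s, 72]: min alpha=%.3g min beta=%.3g",
                self.t0, a.min(), b.min(),
            )

    def shapes(self, t):
        """Vectorized (alpha(t), beta(t)); raises for t < t0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0 - 1e-12):
            raise DomainError(f"age {t[t < self.t0].min()} precedes trajectory origin t0={self.t0}")
        dt = t - self.t0
        a = self.b1_alpha * np.exp(-self.a1_alpha * dt) + self.b2_alpha * np.exp(-self.a2_alpha * dt)
        b = self.b1_beta * np.exp(-self.a1_beta * dt) + self.b2_beta * np.exp(-self.a2_beta * dt)
        return a, b

    def __call__(self, t: float) -> tuple[float, float]:
        a, b = self.shapes(t)
        return float(a), float(b)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ShapeTrajectory":
        with open(path) as fh:
            return cls(**json.load(fh))


def eval_trajectory(traj: ShapeTrajectory, t) -> tuple[float, float]:
    """(alpha(t), beta(t)) at age ``t`` (weeks); t must be >= traj.t0."""
    return traj(t)


def constant_trajectory(alpha: float, beta: float, t0: float = 0.0) -> ShapeTrajectory:
    """Trajectory evaluating to a fixed (alpha, beta) at every age — handy
    for age-independent distributions such as Beta(1, 1)."""
    if alpha <= 0 or beta <= 0:
        raise ValidationError("shape parameters must be positive")
    return ShapeTrajectory(t0, alpha, 0.0, 0.0, 0.0, beta, 0.0, 0.0, 0.0)


def _biexp(dt: np.ndarray, p: np.ndarray) -> np.ndarray:
    b1, a1, b2, a2 = p
    return b1 * np.exp(-a1 * dt) + b2 * np.exp(-a2 * dt)


#: Box for (b1, a1, b2, a2): amplitudes nonnegative (the curve then stays
#: positive for every rate sign); rates capped to keep exp() finite when
#: extrapolating to 72 weeks.
_CURVE_LB = np.array([0.0, -0.3, 0.0, -0.3])
_CURVE_UB = np.array([np.inf, 50.0, np.inf, 50.0])


def _fit_one_curve(dt: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares biexponential fit of y(dt); returns (b1, a1, b2, a2)
    with a1 >= a2."""
    span = dt.max() - dt.min() if dt.max() > dt.min() else 1.0
    rates = np.geomspace(0.005, 50.0 / span, 5)
    splits = (0.25, 0.5, 0.75, 1.0)
    y0 = max(y[0], 1e-6)

    best = None
    for r1 in rates:
        for frac in splits:
            r2 = r1 / 20.0
            p0 = np.clip(np.array([y0 * frac, r1, y0 * (1 - frac), r2]),
                         _CURVE_LB + 1e-12, np.minimum(_CURVE_UB, 1e12))
            res = least_squares(lambda p: _biexp(dt, p) - y, p0, method="trf",
                                bounds=(_CURVE_LB, _CURVE_UB), xtol=1e-14, ftol=1e-14,
                                max_nfev=2000)
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise OptimizationError("biexponential fit failed on every start", best=best)
    b1, a1, b2, a2 = best.x
    if a1 < a2:  # enforce fast-component-first convention
        b1, a1, b2, a2 = b2, a2, b1, a1
    return np.array([b1, a1, b2, a2])


def fit_trajectory(estimates: Sequence[AgeShapeEstimate], t0: float | None = None) -> ShapeTrajectory:
    """Fit alpha(t) and beta(t) biexponentials to per-age shape estimates.

    The two curves are fitted independently by unweighted least squares.
    ``t0`` defaults to the smallest estimated age and must equal it when
    given.  Requires at least 4 distinct ages (4 parameters per curve).
    """
    if len({e.age_weeks for e in estimates}) < 4:
        raise ValidationError("need estimates at >= 4 distinct ages to fit a biexponential")
    est = sorted(estimates, key=lambda e: e.age_weeks)
    ages = np.array([e.age_weeks for e in est])
    if t0 is None:
        t0 = float(ages[0])
    elif abs(t0 - ages[0]) > 1e-9:
        raise ValidationError(f"t0={t0} must equal the smallest estimated age {ages[0]}")
    dt = ages - t0
    pa = _fit_one_curve(dt, np.array([e.alpha for e in est]))
    pb = _fit_one_curve(dt, np.array([e.beta for e in est]))
    return ShapeTrajectory(t0, *pa, *pb)


def trajectory_ssr(traj: ShapeTrajectory, estimates: Sequence[AgeShapeEstimate]) -> float:
    """Sum of squared residuals of the trajectory against per-age estimates
    (both curves)."""
    ages = np.array([e.age_weeks for e in estimates])
    a, b = traj.shapes(ages)
    ra = a - np.array([e.alpha for e in estimates])
    rb = b - np.array([e.beta for e in estimates])
    return float(ra @ ra + rb @ rb)
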