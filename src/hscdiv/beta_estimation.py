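"""Per-age maximum-likelihood fits of the beta distribution.

Each age group's well proportions x_1..x_n (pooled across mice) are modelled
as i.i.d. draws from Beta(alpha_t, beta_t) with density

    f(x) = x**(alpha-1) * (1-x)**(beta-1) / B(alpha, beta).

Exact 0s and 1s (wells in which no, or only, CD201+CD150+KSL cells were
seen) are clamped to 0.001 and 0.999 before fitting so the log-likelihood
stays finite.  Maximization is performed in (log alpha, log beta) — smooth
and unconstrained — starting from the method-of-moments estimate with a
small number of deterministic jittered restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma

from .data_io import WellProportionTable
from .errors import DegenerateSampleError, OptimizationError, ValidationError

logger = logging.getLogger(__name__)

CLAMP_LO = 0.001
CLAMP_HI = 0.999

_GRAD_TOL = 1e-8
_N_RESTARTS = 3
_RESTART_SEED = 20240129


def clamp_proportions(xs, lo: float = CLAMP_LO, hi: float = CLAMP_HI) -> np.ndarray:
    """Replace exact 0s by ``lo`` and exact 1s by ``hi``; interior values pass
    through unchanged."""
    xs = np.asarray(xs, dtype=float)
    if np.any((xs < 0) | (xs > 1)):
        bad = np.flatnonzero((xs < 0) | (xs > 1))
        raise ValidationError(f"proportions outside [0, 1] at position(s) {bad.tolist()}")
    out = xs.copy()
    out[xs == 0.0] = lo
    out[xs == 1.0] = hi
    return out


def _moment_estimate(xs: np.ndarray) -> tuple[float, float]:
    """Method-of-moments start point: match sample mean and variance."""
    m = xs.mean()
    v = xs.var(ddof=1)
    v = min(v, m * (1 - m) * 0.999)  # keep the common factor positive
    common = m * (1 - m) / v - 1.0
    return max(m * common, 1e-3), max((1 - m) * common, 1e-3)


def beta_log_likelihood(xs: np.ndarray, alpha: float, beta: float) -> float:
    """Sum of log Beta(alpha, beta) densities over ``xs``."""
    n = len(xs)
    return float(
        (alpha - 1) * np.log(xs).sum()
        + (beta - 1) * np.log1p(-xs).sum()
        - n * betaln(alpha, beta)
    )


def fit_beta_mle(xs) -> tuple[float, float, float]:
    """Maximum-likelihood (alpha, beta) for strictly interior proportions.

    Returns ``(alpha_hat, beta_hat, log_likelihood)``.  Raises
    :class:`DegenerateSampleError` when all observations coincide (the
    likelihood is then unbounded) and :class:`OptimizationError` if no
    restart converges.
    """
    xs = np.asarray(xs, dtype=float)
    if len(xs) < 2:
        raise ValidationError(f"need at least 2 observations, got {len(xs)}")
    if np.any((xs <= 0) | (xs >= 1)):
        raise ValidationError("observations must lie strictly in (0, 1); clamp first")
    if np.ptp(xs) == 0.0:
        raise DegenerateSampleError(
            f"all {len(xs)} observations equal {xs[0]}; beta likelihood is unbounded"
        )

    n = len(xs)
    slog = np.log(xs).sum()
    slog1m = np.log1p(-xs).sum()

    def neg_ll(theta):
        a, b = np.exp(theta)
        return -((a - 1) * slog + (b - 1) * slog1m - n * betaln(a, b))

    def neg_grad(theta):
        a, b = np.exp(theta)
        dpsi = digamma(a + b)
        ga = slog - n * (digamma(a) - dpsi)
        gb = slog1m - n * (digamma(b) - dpsi)
        return -np.array([ga * a, gb * b])  # chain rule through log-parameters

    a0, b0 = _moment_estimate(xs)
    rng = np.random.default_rng(_RESTART_SEED)
    starts = [np.log([a0, b0])]
    for _ in range(_N_RESTARTS):
        starts.append(np.log([a0, b0]) + rng.normal(scale=0.5, size=2))

    best = None
    for theta0 in starts:
        res = minimize(neg_ll, theta0, jac=neg_grad, method="BFGS",
                       options={"gtol": _GRAD_TOL, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise OptimizationError("beta MLE failed to converge", best=best)
    alpha, beta = np.exp(best.x)
    return float(alpha), float(beta), float(-best.fun)


@dataclass(frozen=True)
class AgeShapeEstimate:
    """MLE shape pair for one age group."""

    age_weeks: float
    alpha: float
    beta: float
    log_likelihood: float
    n_wells: int

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValidationError(f"shape parameters must be positive, got {self.alpha}, {self.beta}")
        if not np.isfinite(self.log_likelihood):
            raise ValidationError("log-likelihood must be finite")


def fit_all_ages(table: WellProportionTable) -> list[AgeShapeEstimate]:
    """One beta MLE per distinct age, pooling wells across mice.

    Ages with fewer than 2 wells, or whose wells are all identical after
    clamping, are skipped with a logged warning.  Output is sorted by age.
    """
    out: list[AgeShapeEstimate] = []
    for age, grp in sorted(table.df.groupby("age_weeks"), key=lambda kv: kv[0]):
        xs = grp["proportion"].to_numpy()
        if len(xs) < 2:
            logger.warning("age %s: only %d well(s); skipping beta fit", age, len(xs))
            continue
        try:
            a, b, ll = fit_beta_mle(clamp_proportions(xs))
        except DegenerateSampleError as exc:
            logger.warning("age %s: %s; skipping beta fit", age, exc)
            continue
        out.append(AgeShapeEstimate(float(age), a, b, ll, int(len(xs))))
    return out
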