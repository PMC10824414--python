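"""Division-mode fractions from the discretized beta distribution.

The proportion axis [0, 1] is cut into ten bins of width 0.1.  Two
thresholds c1 < c2 on that grid classify the first division of a cultured
HSC by the well's final CD201+CD150+KSL proportion x:

    P-P (symmetric differentiation)  x < c1
    S-P (asymmetric)                 c1 < x < c2
    S-S (symmetric self-renewal)     x > c2

At age t the fractions are read off the discretized CDF of
Beta(alpha(t), beta(t)):

    p(t)  = 1 - P_c2          (S-S)
    q(t)  = P_c2 - P_c1       (S-P)
    pp(t) = P_c1              (P-P)

where P_c sums the bin masses I_{x+0.1} - I_x below c; by telescoping this
equals the continuous regularized incomplete beta I_c exactly.  The
discretized (grid-restricted) form is deliberate: it forbids thresholds
below 0.1, which a continuous fit can drive to implausibly small values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .errors import DomainError, ValidationError
from .shape_dynamics import ShapeTrajectory

GRID_STEP = 0.1
#: Left edges of the ten proportion bins.
BIN_EDGES = tuple(round(i * GRID_STEP, 1) for i in range(10))
#: Admissible threshold values.
THRESHOLD_GRID = tuple(round(i * GRID_STEP, 1) for i in range(1, 10))


def _grid_index(x: float, grid: tuple, what: str) -> int:
    k = round(x / GRID_STEP)
    if abs(x - k * GRID_STEP) > 1e-9 or round(k * GRID_STEP, 1) not in grid:
        raise DomainError(f"{what}={x} is not on the 0.1 grid {grid}")
    return k


@dataclass(frozen=True)
class DivisionThresholds:
    """Grid thresholds (c1, c2) separating P-P / S-P / S-S divisions."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        _grid_index(self.c1, THRESHOLD_GRID, "c1")
        _grid_index(self.c2, THRESHOLD_GRID, "c2")
        if not self.c1 < self.c2:
            raise ValidationError(f"thresholds must satisfy c1 < c2, got ({self.c1}, {self.c2})")

    @staticmethod
    def all_pairs() -> list["DivisionThresholds"]:
        """All 36 admissible (c1, c2) combinations, ordered lexicographically."""
        return [
            DivisionThresholds(c1, c2)
            for c1 in THRESHOLD_GRID
            for c2 in THRESHOLD_GRID
            if c1 < c2
        ]


@dataclass(frozen=True)
class DivisionFractions:
    """Probability vector (p, q, pp) of S-S / S-P / P-P divisions at one age."""

    age_weeks: float
    p: float
    q: float
    pp: float

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("q", self.q), ("pp", self.pp)):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if abs(self.p + self.q + self.pp - 1.0) > 1e-12:
            raise ValidationError(f"fractions sum to {self.p + self.q + self.pp}, not 1")


def discretized_bin_mass(traj: ShapeTrajectory, t: float, x_lo: float) -> float:
    """Mass of Beta(alpha(t), beta(t)) on the bin [x_lo, x_lo + 0.1]."""
    _grid_index(x_lo, BIN_EDGES, "x_lo")
    a, b = traj(t)
    hi = betainc(a, b, min(x_lo + GRID_STEP, 1.0))
    lo = betainc(a, b, x_lo) if x_lo > 0 else 0.0
    return float(hi - lo)


def cumulative_below(traj: ShapeTrajectory, t: float, c: float) -> float:
    """Discretized CDF P_c: total mass of the bins below threshold ``c``.

    Computed as the sum of bin masses (the discretized route); by
    telescoping it coincides with the continuous CDF I_c(alpha(t), beta(t))
    to floating-point roundoff.
    """
    k = _grid_index(c, THRESHOLD_GRID, "c")
    return float(sum(discretized_bin_mass(traj, t, round(i * GRID_STEP, 1)) for i in range(k)))


def _fractions_ab(a: float, b: float, thr: DivisionThresholds) -> tuple[float, float, float]:
    P1 = float(betainc(a, b, thr.c1))
    P2 = float(betainc(a, b, thr.c2))
    return 1.0 - P2, P2 - P1, P1


def division_fractions_at(
    traj: ShapeTrajectory, t: float, thr: DivisionThresholds
) -> DivisionFractions:
    """(p, q, pp) at age ``t`` under thresholds ``thr``."""
    a, b = traj(t)
    p, q, pp = _fractions_ab(a, b, thr)
    return DivisionFractions(float(t), p, q, pp)


def fraction_timecourse(
    traj: ShapeTrajectory, thr: DivisionThresholds, ages
) -> list[DivisionFractions]:
    """Division fractions evaluated on a grid of ages."""
    return [division_fractions_at(traj, float(t), thr) for t in np.asarray(ages, dtype=float)]
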