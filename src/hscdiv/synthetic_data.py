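"""Synthetic studies with known ground truth.

The generator emulates the reference study design end to end:

* *ex vivo*: per-well CD201+CD150+KSL proportions drawn from the
  age-dependent beta distribution Beta(alpha(t), beta(t)) at eleven ages
  between 4 and 52 weeks, with the per-age mouse counts of the original
  design and 60 wells per mouse (the wells-per-mouse count is an assumption
  of this generator, recorded in truth.json);
* *in vivo*: HSC and KSL counts for femur, pelvis and sternum at seven ages
  between 6 and 72 weeks, three mice per age, generated from the
  two-compartment ODE with multiplicative lognormal observation noise
  (sigma = 0.05 by default, matching the order of the reported scatter).

The default truth trajectory is anchored so that, at thresholds
(c1, c2) = (0.3, 0.8), the S-S fraction is 52.4% at 10 weeks and 41.6% at
70 weeks and the P-P fraction 24.9% / 41.5% — the study's headline
fractions — with biexponential decay rates chosen so the S-S fraction
declines monotonically and the simulated HSC count roughly triples from
6 to 72 weeks before plateauing.  Truth ODE parameters are the study's
point estimates (r = 0.172 / week, S0 = 5140, P0 = 101000, d = 0.1 / week).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import BONES, CensusSeries, WellProportionTable
from .division_fractions import DivisionThresholds
from .errors import ValidationError
from .population_model import ModelParams, model_counts
from .shape_dynamics import ShapeTrajectory

#: Ex vivo ages (weeks) and number of mice sampled at each.
EXVIVO_DESIGN = {4: 3, 5: 3, 6: 5, 7: 3, 8: 3, 9: 3, 15: 1, 20: 4, 22: 1, 48: 3, 52: 1}
#: In vivo census ages (weeks); three mice per age.
INVIVO_AGES = (6, 15, 20, 25, 40, 52, 72)

#: Truth shape trajectory: biexponential curves through the shape pairs
#: uniquely determined by the headline division fractions at 10 and 70
#: weeks (see module docstring).
DEFAULT_TRAJECTORY = ShapeTrajectory(
    t0=4.0,
    b1_alpha=0.27666253395862583, a1_alpha=0.05,
    b2_alpha=0.21680046402740788, a2_alpha=0.002,
    b1_beta=0.015011678985419816, a1_beta=0.05,
    b2_beta=0.21047281579983518, a2_beta=0.002,
)

DEFAULT_THRESHOLDS = DivisionThresholds(0.3, 0.8)
DEFAULT_ODE_PARAMS = ModelParams(r=0.172, d=0.1, S0=5.14e3, P0=1.01e5, t0=4.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete recipe for one synthetic study.

    ``census_sigma`` is the lognormal observation noise (natural-log scale)
    on counts; ``cells_per_well`` switches on beta-binomial quantization of
    well proportions (None = record the beta draw itself).
    """

    trajectory: ShapeTrajectory = DEFAULT_TRAJECTORY
    thresholds: DivisionThresholds = DEFAULT_THRESHOLDS
    ode_params: ModelParams = DEFAULT_ODE_PARAMS
    ages_exvivo: dict = field(default_factory=lambda: dict(EXVIVO_DESIGN))
    wells_per_mouse: int = 60
    ages_invivo: tuple = INVIVO_AGES
    mice_per_age_invivo: int = 3
    census_sigma: float = 0.05
    cells_per_well: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells_per_mouse < 1 or self.mice_per_age_invivo < 1:
            raise ValidationError("design counts must be >= 1")
        if any(n < 1 for n in self.ages_exvivo.values()):
            raise ValidationError("mice per ex vivo age must be >= 1")
        if self.census_sigma < 0:
            raise ValidationError("census_sigma must be >= 0")
        if self.cells_per_well is not None and self.cells_per_well < 1:
            raise ValidationError("cells_per_well must be >= 1 when set")

    def truth_dict(self) -> dict:
        return {
            "trajectory": asdict(self.trajectory),
            "thresholds": {"c1": self.thresholds.c1, "c2": self.thresholds.c2},
            "ode_params": asdict(self.ode_params),
            "design": {
                "ages_exvivo": {str(k): v for k, v in self.ages_exvivo.items()},
                "wells_per_mouse": self.wells_per_mouse,
                "ages_invivo": list(self.ages_invivo),
                "mice_per_age_invivo": self.mice_per_age_invivo,
            },
            "noise": {"census_sigma": self.census_sigma, "cells_per_well": self.cells_per_well},
            "seed": self.seed,
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2)


def paper_like_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """The default spec mirroring the reference study design; keyword
    overrides replace individual fields."""
    return GeneratorSpec(seed=seed, **overrides)


def generate_wells(spec: GeneratorSpec) -> WellProportionTable:
    """Draw per-well proportions from the truth beta distributions.

    With ``cells_per_well`` set, each well reports k/n with
    k ~ Binomial(n, x), so exact 0s and 1s occur and exercise the clamping
    path downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rows = []
    for age in sorted(spec.ages_exvivo):
        a, b = spec.trajectory(float(age))
        for m in range(spec.ages_exvivo[age]):
            for w in range(spec.wells_per_mouse):
                x = rng.beta(a, b)
                if spec.cells_per_well is not None:
                    x = rng.binomial(spec.cells_per_well, x) / spec.cells_per_well
                rows.append(
                    {"age_weeks": float(age), "mouse_id": f"m{m + 1}",
                     "well_id": f"w{w + 1}", "proportion": float(x)}
                )
    return WellProportionTable(pd.DataFrame(rows))


def generate_census(spec: GeneratorSpec) -> CensusSeries:
    """Simulate the in vivo census: true (S, KSL) from the ODE, observed
    with multiplicative lognormal noise, independently per bone and mouse.
    Draws violating hsc <= ksl are resampled."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    ages = np.asarray(spec.ages_invivo, dtype=float)
    S, KSL = model_counts(spec.ode_params, spec.trajectory, spec.thresholds, ages)
    rows = []
    for bone in BONES:
        for age, s_true, ksl_true in zip(ages, S, KSL):
            for m in range(spec.mice_per_age_invivo):
                for _ in range(1000):
                    hsc = s_true * rng.lognormal(0.0, spec.census_sigma)
                    ksl = ksl_true * rng.lognormal(0.0, spec.census_sigma)
                    if hsc <= ksl:
                        break
                rows.append(
                    {"age_weeks": float(age), "bone": bone, "mouse_id": f"m{m + 1}",
                     "hsc_count": float(hsc), "ksl_count": float(ksl)}
                )
    return CensusSeries(pd.DataFrame(rows))
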