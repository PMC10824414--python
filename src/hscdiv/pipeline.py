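"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` executes: per-age beta MLE -> biexponential shape
trajectory -> threshold grid search with NLS -> MCMC posteriors ->
d-sensitivity scan, writing every intermediate artifact as delimited text
so each stage can be rerun or audited in isolation:

    shapes.csv       per-age (alpha, beta) MLEs
    trajectory.json  biexponential parameters + t0
    ssr_grid.csv     36-row SSR audit table
    fit_summary.csv  winning thresholds, point estimates, 95% CIs, SSR
    posterior.csv    MCMC samples of (r, S0, P0)
    fractions.csv    division-fraction time course at the winning thresholds
    sensitivity.csv  SSR per d (when more than one d is configured)
    manifest.json    config hash, seed, package version

A stage failure writes a FAILED marker naming the stage and re-raises;
artifacts produced before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .beta_estimation import fit_all_ages
from .data_io import read_census, read_well_proportions, write_table
from .division_fractions import fraction_timecourse
from .inference import FitConfig, fit_model
from .shape_dynamics import fit_trajectory

logger = logging.getLogger(__name__)

FRACTION_AGE_MAX = 72.0


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus the inference settings forwarded to :class:`FitConfig`."""

    wells: str
    census: str
    outdir: str
    t0: float | None = None          # None: first age in the wells table
    bone: str = "femur"
    d_values: tuple = (0.1,)
    loss_scale: str = "log10"
    n_chains: int = 4
    n_steps: int = 50_000
    n_burn: int = 10_000
    seed: int = 0
    with_mcmc: bool = True

    def fit_config(self) -> FitConfig:
        return FitConfig(
            d_values=tuple(self.d_values), loss_scale=self.loss_scale, bone=self.bone,
            n_chains=self.n_chains, n_steps=self.n_steps, n_burn=self.n_burn, seed=self.seed,
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig):
    """Run all stages; returns the :class:`~hscdiv.inference.ModelFit`."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t_start = time.time()
    try:
        stage = "fit-beta"
        wells = read_well_proportions(cfg.wells)
        census = read_census(cfg.census)
        estimates = fit_all_ages(wells)
        shapes = pd.DataFrame(
            [{"age_weeks": e.age_weeks, "alpha": e.alpha, "beta": e.beta,
              "log_likelihood": e.log_likelihood, "n_wells": e.n_wells} for e in estimates]
        )
        write_table(shapes, out / "shapes.csv")
        logger.info("[%s] %d age groups fitted (%.1fs)", stage, len(shapes), time.time() - t_start)

        stage = "fit-shapes"
        traj = fit_trajectory(estimates, cfg.t0)
        traj.to_json(out / "trajectory.json")

        stage = "grid-search"
        fit = fit_model(traj, census, cfg.fit_config(), with_mcmc=False)
        write_table(fit.ssr_table, out / "ssr_grid.csv")
        logger.info("[%s] best (c1, c2) = (%s, %s), SSR = %.4g (%.1fs)", stage,
                    fit.thresholds.c1, fit.thresholds.c2, fit.ssr, time.time() - t_start)

        if cfg.with_mcmc:
            stage = "mcmc"
            from .inference import run_mcmc

            fit.posterior = run_mcmc(fit.thresholds, traj, census, cfg.fit_config(), fit.params_point)
            write_table(fit.posterior.samples, out / "posterior.csv")

        stage = "sensitivity"
        if len(cfg.d_values) > 1:
            from .inference import sensitivity_d

            fit.sensitivity = sensitivity_d(fit.thresholds, traj, census, cfg.fit_config())
            write_table(fit.sensitivity, out / "sensitivity.csv")

        stage = "summaries"
        p = fit.params_point
        rows = [
            {"parameter": "c1", "value": fit.thresholds.c1, "ci_lo": "", "ci_hi": ""},
            {"parameter": "c2", "value": fit.thresholds.c2, "ci_lo": "", "ci_hi": ""},
            {"parameter": "d", "value": p.d, "ci_lo": "", "ci_hi": ""},
            {"parameter": "ssr", "value": fit.ssr, "ci_lo": "", "ci_hi": ""},
        ]
        for name, point_val in (("r", p.r), ("S0", p.S0), ("P0", p.P0)):
            row = {"parameter": name, "value": point_val, "ci_lo": "", "ci_hi": ""}
            if fit.posterior is not None:
                s = fit.posterior.summaries.loc[name]
                row = {"parameter": name, "value": s["mean"], "ci_lo": s["ci_lo"], "ci_hi": s["ci_hi"]}
            rows.append(row)
        write_table(pd.DataFrame(rows), out / "fit_summary.csv")

        ages = np.arange(traj.t0, FRACTION_AGE_MAX + 0.5, 1.0)
        fracs = fraction_timecourse(traj, fit.thresholds, ages)
        write_table(
            pd.DataFrame([{"age_weeks": f.age_weeks, "p_ss": f.p, "q_sp": f.q, "pp": f.pp}
                          for f in fracs]),
            out / "fractions.csv",
        )

        from . import __version__ as pkg_version

        manifest = {
            "package_version": pkg_version,
            "config": dataclasses.asdict(cfg),
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "elapsed_s": round(time.time() - t_start, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return fit
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
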