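import numpy as np
import pandas as pd
import pytest

from hscdiv.data_io import CensusSeries
from hscdiv.division_fractions import DivisionThresholds
from hscdiv.errors import DomainError, ValidationError
from hscdiv.inference import (
    FitConfig,
    fit_point,
    grid_search_thresholds,
    run_mcmc,
    sensitivity_d,
    ssr_objective,
)
from hscdiv.population_model import ModelParams
from hscdiv.synthetic_data import generate_census, paper_like_spec

CFG = FitConfig(seed=3)
SHORT_MCMC = dict(n_chains=2, n_steps=4000, n_burn=1500)


class TestSsrObjective:
    def test_self_fit_is_zero(self, census_noisefree, truth_traj, truth_thr, truth_params):
        assert ssr_objective(truth_params, truth_thr, truth_traj, census_noisefree, CFG) <= 1e-12

    def test_perturbing_r_increases_ssr(self, census_noisefree, truth_traj, truth_thr, truth_params):
        base = ssr_objective(truth_params, truth_thr, truth_traj, census_noisefree, CFG)
        for factor in (0.8, 1.2):
            bumped = ModelParams(r=truth_params.r * factor, d=truth_params.d,
                                 S0=truth_params.S0, P0=truth_params.P0, t0=truth_params.t0)
            assert ssr_objective(bumped, truth_thr, truth_traj, census_noisefree, CFG) > base

    def test_noise_raises_ssr_toward_expected_level(self, truth_traj, truth_thr, truth_params):
        """E[SSR] at truth params ~ n * (sigma/ln10)^2 for lognormal noise;
        doubling sigma quadruples it."""
        ssrs = {}
        for sigma in (0.05, 0.10):
            vals = [
                ssr_objective(
                    truth_params, truth_thr, truth_traj,
                    generate_census(paper_like_spec(seed=s, census_sigma=sigma)), CFG,
                )
                for s in range(8)
            ]
            ssrs[sigma] = np.mean(vals)
        assert ssrs[0.10] / ssrs[0.05] == pytest.approx(4.0, rel=0.4)

    def test_census_before_t0_rejected(self, truth_traj, truth_thr, truth_params):
        df = pd.DataFrame(
            [(2.0, "femur", "m1", 100.0, 1000.0)],
            columns=["age_weeks", "bone", "mouse_id", "hsc_count", "ksl_count"],
        )
        with pytest.raises(DomainError):
            ssr_objective(truth_params, truth_thr, truth_traj, CensusSeries(df), CFG)


class TestFitPoint:
    def test_noise_free_recovery_is_exact(self, census_noisefree, truth_traj, truth_thr):
        params, ssr = fit_point(truth_thr, truth_traj, census_noisefree, CFG)
        assert ssr < 1e-12
        assert params.r == pytest.approx(0.172, rel=1e-4)
        assert params.S0 == pytest.approx(5.14e3, rel=1e-4)
        assert params.P0 == pytest.approx(1.01e5, rel=1e-4)

    def test_noisy_recovery_within_25pct(self, census_noisy, truth_traj, truth_thr):
        params, _ = fit_point(truth_thr, truth_traj, census_noisy, CFG)
        assert abs(params.r / 0.172 - 1) < 0.25


class TestGridSearch:
    def test_audit_table_exhaustive_and_consistent(self, census_noisy, truth_traj):
        fit = grid_search_thresholds(truth_traj, census_noisy, CFG)
        assert len(fit.ssr_table) == 36
        assert fit.ssr == fit.ssr_table["ssr"].min()
        pairs = set(zip(fit.ssr_table["c1"], fit.ssr_table["c2"]))
        assert all(c1 < c2 for c1, c2 in pairs) and len(pairs) == 36

    def test_recovers_generating_thresholds_at_low_noise(self, truth_traj):
        census = generate_census(paper_like_spec(seed=2, census_sigma=0.01))
        fit = grid_search_thresholds(truth_traj, census, CFG)
        assert (fit.thresholds.c1, fit.thresholds.c2) == (0.3, 0.8)


class TestMcmc:
    def test_seed_reproducibility_bit_identical(self, census_noisy, truth_traj, truth_thr):
        cfg = FitConfig(seed=11, n_chains=2, n_steps=1200, n_burn=400)
        point, _ = fit_point(truth_thr, truth_traj, census_noisy, cfg)
        res1 = run_mcmc(truth_thr, truth_traj, census_noisy, cfg, point)
        res2 = run_mcmc(truth_thr, truth_traj, census_noisy, cfg, point)
        assert res1.samples.equals(res2.samples)

    def test_acceptance_rate_and_rhat(self, census_noisy, truth_traj, truth_thr):
        cfg = FitConfig(seed=5, **SHORT_MCMC)
        point, _ = fit_point(truth_thr, truth_traj, census_noisy, cfg)
        res = run_mcmc(truth_thr, truth_traj, census_noisy, cfg, point)
        assert 0.1 <= res.acceptance_rate <= 0.6
        assert all(v < 1.05 for v in res.rhat.values())
        assert res.converged

    def test_ci_contains_posterior_mean(self, census_noisy, truth_traj, truth_thr):
        cfg = FitConfig(seed=5, **SHORT_MCMC)
        point, _ = fit_point(truth_thr, truth_traj, census_noisy, cfg)
        res = run_mcmc(truth_thr, truth_traj, census_noisy, cfg, point)
        for name in ("r", "S0", "P0"):
            s = res.summaries.loc[name]
            assert s["ci_lo"] <= s["mean"] <= s["ci_hi"]

    def test_zero_noise_posterior_collapses_to_point(self, census_noisefree, truth_traj, truth_thr):
        cfg = FitConfig(seed=5, n_chains=2, n_steps=1500, n_burn=500)
        point, _ = fit_point(truth_thr, truth_traj, census_noisefree, cfg)
        res = run_mcmc(truth_thr, truth_traj, census_noisefree, cfg, point)
        s = res.summaries.loc["r"]
        assert (s["ci_hi"] - s["ci_lo"]) / point.r < 0.05  # proposal-limited width


class TestSensitivity:
    def test_one_row_per_d_and_truth_d_fits_best(self, truth_traj, truth_thr):
        census = generate_census(paper_like_spec(seed=4, census_sigma=0.01))
        cfg = FitConfig(seed=4, d_values=(0.1, 0.05, 0.2))
        table = sensitivity_d(truth_thr, truth_traj, census, cfg)
        assert list(table["d"]) == [0.1, 0.05, 0.2]
        assert table.loc[table["d"] == 0.1, "ssr"].iloc[0] == table["ssr"].min()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"loss_scale": "log2"},
            {"bone": "skull"},
            {"d_values": (0.1, -0.05)},
            {"n_steps": 100, "n_burn": 100},
            {"r_bounds": (0.5, 0.1)},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FitConfig(**kwargs)
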