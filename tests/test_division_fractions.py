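import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import betainc
from scipy.stats import beta as beta_dist

from hscdiv.division_fractions import (
    BIN_EDGES,
    THRESHOLD_GRID,
    DivisionFractions,
    DivisionThresholds,
    cumulative_below,
    discretized_bin_mass,
    division_fractions_at,
    fraction_timecourse,
)
from hscdiv.errors import DomainError, ValidationError
from hscdiv.shape_dynamics import constant_trajectory

UNIFORM = constant_trajectory(1.0, 1.0)


class TestThresholds:
    def test_all_pairs_count(self):
        assert len(DivisionThresholds.all_pairs()) == 36

    @pytest.mark.parametrize("c1, c2", [(0.25, 0.8), (0.3, 0.3), (0.8, 0.3), (0.0, 0.5), (0.3, 1.0)])
    def test_invalid_pairs_rejected(self, c1, c2):
        with pytest.raises((DomainError, ValidationError)):
            DivisionThresholds(c1, c2)


class TestBinMass:
    def test_uniform_bin_mass(self):
        assert discretized_bin_mass(UNIFORM, 1.0, 0.3) == pytest.approx(0.1, abs=1e-14)

    def test_bins_sum_to_one(self):
        traj = constant_trajectory(0.42, 0.22)
        total = sum(discretized_bin_mass(traj, 1.0, x) for x in BIN_EDGES)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature(self):
        traj = constant_trajectory(2.0, 5.0)
        expected, _ = quad(lambda x: beta_dist.pdf(x, 2.0, 5.0), 0.0, 0.1, epsabs=1e-13)
        assert discretized_bin_mass(traj, 1.0, 0.0) == pytest.approx(expected, abs=1e-10)

    def test_off_grid_rejected(self):
        with pytest.raises(DomainError):
            discretized_bin_mass(UNIFORM, 1.0, 0.35)


class TestCumulative:
    def test_uniform(self):
        assert cumulative_below(UNIFORM, 1.0, 0.3) == pytest.approx(0.3, abs=1e-14)

    def test_complement_of_last_bin(self):
        traj = constant_trajectory(0.7, 1.3)
        last = discretized_bin_mass(traj, 1.0, 0.9)
        assert cumulative_below(traj, 1.0, 0.9) == pytest.approx(1.0 - last, abs=1e-12)

    def test_telescoping_identity_random_shapes(self, rng):
        """Discretized CDF equals the continuous regularized incomplete beta
        at every grid threshold (100 random shape pairs)."""
        for _ in range(100):
            a, b = np.exp(rng.uniform(np.log(0.05), np.log(20.0), size=2))
            traj = constant_trajectory(a, b)
            for c in THRESHOLD_GRID:
                assert abs(cumulative_below(traj, 1.0, c) - betainc(a, b, c)) < 1e-12

    @given(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=-3, max_value=3),
        st.sampled_from(THRESHOLD_GRID),
    )
    @settings(derandomize=True, max_examples=60)
    def test_telescoping_identity_property(self, la, lb, c):
        a, b = float(np.exp(la)), float(np.exp(lb))
        traj = constant_trajectory(a, b)
        assert abs(cumulative_below(traj, 1.0, c) - betainc(a, b, c)) < 1e-12


class TestFractions:
    def test_uniform_with_default_thresholds(self):
        fr = division_fractions_at(UNIFORM, 1.0, DivisionThresholds(0.3, 0.8))
        assert (fr.p, fr.q, fr.pp) == pytest.approx((0.2, 0.5, 0.3), abs=1e-12)

    def test_concentrated_distribution_is_all_self_renewal(self):
        fr = division_fractions_at(constant_trajectory(500.0, 1.0), 1.0, DivisionThresholds(0.3, 0.8))
        assert fr.p > 0.999

    def test_monotone_in_thresholds(self):
        traj = constant_trajectory(0.42, 0.22)
        ps = [division_fractions_at(traj, 1.0, DivisionThresholds(0.1, c2)).p
              for c2 in (0.3, 0.5, 0.7, 0.9)]
        assert all(x >= y - 1e-15 for x, y in zip(ps, ps[1:]))
        pps = [division_fractions_at(traj, 1.0, DivisionThresholds(c1, 0.9)).pp
               for c1 in (0.1, 0.3, 0.5, 0.7)]
        assert all(x <= y + 1e-15 for x, y in zip(pps, pps[1:]))

    def test_probability_vector_along_trajectory(self, truth_traj, truth_thr):
        for fr in fraction_timecourse(truth_traj, truth_thr, np.linspace(4, 72, 35)):
            assert abs(fr.p + fr.q + fr.pp - 1.0) < 1e-12
            assert min(fr.p, fr.q, fr.pp) >= 0

    def test_constant_trajectory_gives_constant_fractions(self):
        traj = constant_trajectory(0.5, 0.5, t0=4.0)
        fr = fraction_timecourse(traj, DivisionThresholds(0.3, 0.8), [4, 30, 72])
        assert len({(f.p, f.q, f.pp) for f in fr}) == 1

    def test_truth_trajectory_headline_fractions(self, truth_traj, truth_thr):
        """S-S declines (52.4% -> 41.6%) and P-P rises (24.9% -> 41.5%)
        between 10 and 70 weeks on the default truth trajectory."""
        f10 = division_fractions_at(truth_traj, 10.0, truth_thr)
        f70 = division_fractions_at(truth_traj, 70.0, truth_thr)
        assert f10.p == pytest.approx(0.524, abs=5e-4)
        assert f70.p == pytest.approx(0.416, abs=5e-4)
        assert f10.pp == pytest.approx(0.249, abs=5e-4)
        assert f70.pp == pytest.approx(0.415, abs=5e-4)
        assert f10.p > f70.p and f10.pp < f70.pp

    def test_invalid_fraction_vector_rejected(self):
        with pytest.raises(ValidationError):
            DivisionFractions(1.0, 0.5, 0.5, 0.5)
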