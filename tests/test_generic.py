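"""Generic spike model: intensity, ISI density, moment relations, coupling."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate

from puffspike.core import ChainModel, build_conditioned_waiting_times, fpt_moments
from puffspike.distributions import ExponentialDist, GEDist
from puffspike.dyk import CellParams
from puffspike.generic import (
    GenericParams, approximation_error, coupling_from_mechanistic,
    cumulative_intensity, generic_moments, isi_density_generic,
    isi_survival_generic, moment_relation, sample_generic_train, spike_intensity,
)
from puffspike.pipeline import ChainConfig, build_cell_chain
from puffspike.simulate import isi_statistics


class TestIntensity:
    def test_zero_at_time_zero(self):
        p = GenericParams(1.0, 0.1, rho=2.0)
        assert spike_intensity(0.0, p) == 0.0

    def test_saturates_at_lambda_inf(self):
        p = GenericParams((1.0, 2.0, 0.5, 1.5), (0.1, 0.2, 0.3, 0.4), rho=2.0)
        expect = 1.0 * 0.1 + 2.0 * 0.2 + 0.5 * 0.3 + 1.5 * 0.4
        assert p.lambda_inf == pytest.approx(expect)
        assert spike_intensity(1e6, p) == pytest.approx(expect, rel=1e-12)

    def test_homogeneous_tetrahedron_asymptote(self):
        p = GenericParams(0.3, 0.05, rho=1.0, n_clusters=4)
        assert p.lambda_inf == pytest.approx(4 * 0.3 * 0.05)

    def test_no_feedback_constant_rate(self):
        p = GenericParams(1.0, 0.5)
        assert spike_intensity(0.0, p) == p.lambda_inf

    def test_validation(self):
        with pytest.raises(ValueError):
            GenericParams(1.0, 1.5)
        with pytest.raises(ValueError):
            GenericParams(-1.0, 0.5)
        with pytest.raises(ValueError):
            GenericParams(1.0, 0.5, rho=0.0)


class TestISIDensity:
    def test_no_feedback_is_exponential(self):
        p = GenericParams(1.0, 0.02, n_clusters=1)
        t = np.linspace(0, 100, 50)
        assert np.allclose(isi_density_generic(t, p), 0.02 * np.exp(-0.02 * t))

    def test_zero_at_origin_for_finite_rho(self):
        p = GenericParams(1.0, 0.5, rho=0.3)
        assert isi_density_generic(0.0, p) == 0.0

    @pytest.mark.parametrize("rho", [0.05, 0.5, 5.0])
    def test_normalised(self, rho):
        p = GenericParams(1.0, 0.1, rho=rho, n_clusters=4)
        total, _ = integrate.quad(lambda t: isi_density_generic(t, p), 0, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestMoments:
    def test_exponential_case(self):
        p = GenericParams(1.0, 0.02, n_clusters=1)
        m = generic_moments(p)
        assert m.mean == pytest.approx(50.0, rel=1e-8)
        assert m.sd == pytest.approx(50.0, rel=1e-7)

    def test_refractory_delay_increases_mean(self):
        p = GenericParams(1.0, 0.1, rho=0.5, n_clusters=4)
        assert generic_moments(p).mean > 1.0 / p.lambda_inf

    def test_matches_thinning_simulation(self):
        p = GenericParams(1.0, 1.0, rho=1.0, n_clusters=1)
        m = generic_moments(p)
        train = sample_generic_train(p, 100_000, seed=3, method="thinning")
        se = train.isis.std() / math.sqrt(len(train.isis))
        assert abs(train.isis.mean() - m.mean) < 3 * se

    def test_cv_below_one_with_feedback_and_one_without(self):
        base = dict(puff_rates=1.0, couplings=0.1, n_clusters=4)
        assert generic_moments(GenericParams(**base)).cv == pytest.approx(1.0, rel=1e-7)
        cvs = [generic_moments(GenericParams(**base, rho=r)).cv for r in (0.1, 0.5, 2.0, 10.0)]
        assert np.all(np.array(cvs) < 1.0)
        assert np.all(np.diff(cvs) > 0)  # cv strictly increases with rho

    def test_t_av_decreasing_in_lambda_and_rho(self):
        t_lam = [generic_moments(GenericParams(1.0, xi, rho=0.5)).mean
                 for xi in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(t_lam) < 0)
        t_rho = [generic_moments(GenericParams(1.0, 0.1, rho=r)).mean
                 for r in (0.1, 0.3, 1.0, 3.0)]
        assert np.all(np.diff(t_rho) < 0)


class TestSampling:
    def test_no_feedback_cv_near_one(self):
        train = sample_generic_train(GenericParams(1.0, 0.05), 20_000, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = isi_statistics(train, n_boot=200, seed=1)
        assert abs(s.cv - 1.0) < 3 * s.se["cv"]

    def test_inversion_matches_analytic_moments(self):
        p = GenericParams(1.0, 0.1, rho=0.2, n_clusters=4)
        m = generic_moments(p)
        train = sample_generic_train(p, 10_000, seed=2)
        se = train.isis.std() / math.sqrt(len(train.isis))
        assert abs(train.isis.mean() - m.mean) < 3 * se

    def test_feedback_lowers_sample_cv(self):
        fast = sample_generic_train(GenericParams(1.0, 0.1, rho=0.05, n_clusters=4),
                                    10_000, seed=4)
        cv = fast.isis.std() / fast.isis.mean()
        assert cv < 0.9

    def test_seed_determinism(self):
        p = GenericParams(1.0, 0.1, rho=0.3)
        a = sample_generic_train(p, 100, seed=9)
        b = sample_generic_train(p, 100, seed=9)
        assert np.array_equal(a.isis, b.isis)


class TestMomentRelation:
    def test_slope_one_without_feedback(self):
        p = GenericParams(1.0, 0.1)
        rel = moment_relation(p, "lambda_inf", [0.005, 0.01, 0.02, 0.05, 0.1])
        assert rel.slope == pytest.approx(1.0, abs=1e-6)
        assert abs(rel.intercept) < 1e-6

    def test_feedback_flattens_slope(self):
        p = GenericParams(1.0, 0.1, rho=0.02, n_clusters=4)
        rel = moment_relation(p, "lambda_inf", [0.005, 0.01, 0.02, 0.05, 0.1])
        assert rel.slope < 1.0
        assert rel.intercept != 0.0

    def test_xi_sweep_moves_along_the_same_relation(self):
        """xi in {0.05, 0.01, 0.008} lands on the sigma-T_av curve of its rho."""
        rho = 0.05
        p = GenericParams(1.0, 0.02, rho=rho, n_clusters=4)
        rel = moment_relation(p, "lambda_inf", np.geomspace(0.004, 0.4, 25))
        pts = np.array(rel.points)
        order = np.argsort(pts[:, 0])
        for xi in (0.05, 0.01, 0.008):
            q = GenericParams(1.0, xi, rho=rho, n_clusters=4)
            m = generic_moments(q)
            predicted = np.interp(m.mean, pts[order, 0], pts[order, 1])
            assert m.sd == pytest.approx(predicted, rel=0.01)

    def test_slope_invariant_under_xi_rescaling(self):
        """Rescaling all couplings does not change the fitted slope."""
        rho = 0.05
        lam_values = np.geomspace(0.05, 2.0, 7)
        rel_hi = moment_relation(GenericParams(1.0, 0.2, rho=rho, n_clusters=4),
                                 "lambda", lam_values / 0.8)
        rel_lo = moment_relation(GenericParams(1.0, 0.05, rho=rho, n_clusters=4),
                                 "lambda", lam_values / 0.2)
        assert rel_lo.slope == pytest.approx(rel_hi.slope, rel=1e-6)

    def test_degenerate_sweep_rejected(self):
        with pytest.raises(ValueError):
            moment_relation(GenericParams(1.0, 0.1), "lambda_inf", [0.01])


class TestCoupling:
    def test_certain_escalation_gives_unit_coupling(self):
        chain = ChainModel(4, tuple([ExponentialDist(0.05)] + [ExponentialDist(5e4)] * 3),
                           ExponentialDist(1.0))
        assert coupling_from_mechanistic(chain) == pytest.approx(1.0, abs=1e-3)

    def test_increases_and_saturates_with_ip3(self, param_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xis = [coupling_from_mechanistic(
                build_cell_chain(CellParams(ip3=v), param_map, ChainConfig()))
                for v in (0.2, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(xis) > 0)
        assert xis[-1] > 0.9
        # saturating: the last relative gain is far below the first
        gains = np.diff(xis) / np.array(xis[:-1])
        assert gains[-1] < gains[0] / 5

    def test_increases_and_saturates_with_n_ch(self, param_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xis = [coupling_from_mechanistic(
                build_cell_chain(CellParams(n_ch=n), param_map, ChainConfig()))
                for n in (3, 5, 7, 10, 14, 20)]
        assert np.all(np.diff(xis) > 0)
        assert xis[-1] > 0.95
        assert np.diff(xis)[-1] < np.diff(xis)[0]

    def test_matches_excursion_monte_carlo(self):
        """xi agrees with the fraction of simulated excursions that spike."""
        chain = ChainModel(4, tuple([ExponentialDist(2.0)] + [ExponentialDist(20.0)] * 3),
                           ExponentialDist(10.0))
        xi = coupling_from_mechanistic(chain)
        from puffspike.simulate import simulate_trajectory

        traj = simulate_trajectory(chain, 4000.0, seed=11)
        s = traj.states
        # count excursions leaving 0: success if 4 reached before returning to 0
        succ = tot = 0
        k = 0
        while k < len(s) - 1:
            if s[k] == 0 and s[k + 1] == 1:
                tot += 1
                j = k + 1
                while j < len(s) and s[j] not in (0, 4):
                    j += 1
                if j < len(s) and s[j] == 4:
                    succ += 1
                    while j < len(s) and s[j] != 0:
                        j += 1
                k = j
            else:
                k += 1
        mc = succ / tot
        se = math.sqrt(mc * (1 - mc) / tot)
        assert abs(xi - mc) < 3 * se

    def test_heterogeneous_clusters(self):
        chains = [ChainModel(4, tuple([ExponentialDist(0.05)] + [ExponentialDist(k)] * 3),
                             ExponentialDist(10.0)) for k in (5.0, 20.0)]
        xi = coupling_from_mechanistic(None, per_cluster=chains)
        assert len(xi) == 2 and xi[0] < xi[1]


class TestApproximationError:
    def test_vanishes_for_certain_escalation(self):
        chain = ChainModel(4, tuple([ExponentialDist(0.05)] + [ExponentialDist(5e4)] * 3),
                           ExponentialDist(1e4))
        err = approximation_error([chain])
        assert err["rel_error"].iloc[0] < 1e-2

    def test_requires_exponential_puff_density(self):
        chain = ChainModel(4, tuple([GEDist(2.0, 1.0)] + [ExponentialDist(5.0)] * 3),
                           ExponentialDist(5.0))
        with pytest.raises(ValueError):
            approximation_error([chain])

    def test_intrinsic_minimal_isi_bound(self, param_map):
        """T_av over a growing stimulation sweep stays above 1/lambda_puff."""
        cfg = ChainConfig()
        t_avs, bounds = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ip3 in (0.2, 0.5, 1.0, 2.0, 4.0):
                chain = build_cell_chain(CellParams(ip3=ip3), param_map, cfg)
                cwt = build_conditioned_waiting_times(chain)
                t_avs.append(fpt_moments(cwt, 0, 4).mean)
                bounds.append(1.0 / chain.psi_open[0].lam)
        assert np.all(np.diff(t_avs) < 0)
        assert all(t > b for t, b in zip(t_avs, bounds))
        # saturating stimulation cannot push T_av below the puff-rate floor
        assert min(t_avs) > 0.9 * min(bounds)
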