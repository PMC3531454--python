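"""Semi-Markov engine: conditioned waiting times, occupancy, FPT, splitting."""

import math

import numpy as np
import pytest

from puffspike.core import (
    ChainModel, ChainTopologyError, ConditionedWaitingTimes, TransitionDensity,
    build_conditioned_waiting_times, fpt_moments, splitting_probability,
    stationary_occupancy, transform_table,
)
from puffspike.distributions import ExponentialDist, GEDist
from puffspike.fixtures import conditioned_from_rates, make_fixture_chain


def ctmc_fpt_raw_moments(Q, start, target, n_max=4):
    """Fundamental-matrix oracle: m_n = n! e_start' M^n 1 with M = (-Q_sub)^-1."""
    keep = [i for i in range(Q.shape[0]) if i != target]
    M = np.linalg.inv(-Q[np.ix_(keep, keep)])
    e = np.zeros(len(keep))
    e[keep.index(start)] = 1.0
    ones = np.ones(len(keep))
    out = [1.0]
    v = ones
    for n in range(1, n_max + 1):
        v = M @ v
        out.append(math.factorial(n) * float(e @ v))
    return out


def ctmc_stationary(Q):
    w, V = np.linalg.eig(Q.T)
    p = np.real(V[:, np.argmin(np.abs(w))])
    return np.abs(p) / np.abs(p).sum()


def birth_death_generator(kp, k_open, k_close, N=4):
    Q = np.zeros((N + 1, N + 1))
    Q[0, 1] = kp
    for i in range(1, N):
        Q[i, i + 1] = (N - i) * k_open
        Q[i, i - 1] = i * k_close
    Q[N, N - 1] = N * k_close
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class TestConstruction:
    def test_embedded_weights_for_competing_exponentials(self):
        N, ko, kc = 4, 3.0, 7.0
        chain = ChainModel(N, tuple([ExponentialDist(0.5)] + [ExponentialDist(ko)] * 3),
                           ExponentialDist(kc))
        P = build_conditioned_waiting_times(chain).embedded_matrix()
        for i in range(1, N):
            expected = (N - i) * ko / ((N - i) * ko + i * kc)
            assert P[i, i + 1] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "opening, closing",
        [
            (GEDist(2.0, 5.0), GEDist(5.0, 50.0)),
            (GEDist(0.3, 0.06), GEDist(5.0, 50.0)),   # sub-exponential shape
            (GEDist(0.29, 0.56), GEDist(5.0, 50.0)),
            (ExponentialDist(2.0), GEDist(3.0, 10.0)),
        ],
    )
    def test_row_sums_normalised(self, opening, closing):
        chain = ChainModel(4, tuple([ExponentialDist(0.05)] + [opening] * 3), closing)
        P = build_conditioned_waiting_times(chain).embedded_matrix()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)

    def test_first_opening_much_slower_than_consecutive(self):
        """CICR: the conditioned 1 -> 2 time is far below the 0 -> 1 time."""
        chain = ChainModel(4, tuple([ExponentialDist(0.05)] + [GEDist(0.29, 0.56)] * 3),
                           GEDist(5.0, 50.0))
        cwt = build_conditioned_waiting_times(chain)
        mean01 = cwt.psi(0, 1).moment(1) / cwt.psi(0, 1).moment(0)
        mean12 = cwt.psi(1, 2).moment(1) / cwt.psi(1, 2).moment(0)
        assert mean12 < mean01 / 50

    def test_chain_validation(self):
        with pytest.raises(ValueError):
            ChainModel(1, (ExponentialDist(1.0),), ExponentialDist(1.0))
        with pytest.raises(ValueError):
            ChainModel(3, (ExponentialDist(1.0),) * 2, ExponentialDist(1.0))
        with pytest.raises(ValueError):
            ChainModel(3, (ExponentialDist(1.0),) * 3, ExponentialDist(1.0), target_state=5)


class TestTransformTable:
    def test_exponential_moments(self):
        k = 2.5
        cwt = conditioned_from_rates(np.array([[-k, k], [1.0, -1.0]]))
        tab = transform_table(cwt, order=4)
        m = tab[(0, 1)]["moments"]
        for n in range(5):
            assert m[n] == pytest.approx(math.factorial(n) / k**n, rel=1e-12)

    def test_m0_equals_embedded_weight(self):
        chain = make_fixture_chain("birth_death", {"n_clusters": 4}, seed=0)
        cwt = build_conditioned_waiting_times(chain)
        tab = transform_table(cwt, order=2)
        P = cwt.embedded_matrix()
        for (i, j), entry in tab.items():
            assert entry["moments"][0] == pytest.approx(P[i, j], rel=1e-10)

    def test_ge_series_matches_beta_transform_derivatives(self):
        # single GE transition, no competitors: Psi_hat(s) = a B(1 + s/lam, a)
        d = GEDist(2.3, 4.0)
        td = TransitionDensity(d.pdf, t_hi=d.quantile(1 - 1e-13), alpha=d.a - 1.0,
                               scales=(d.quantile(0.5),))
        c = td.taylor(3)
        h = 1e-3
        for n in range(4):
            s = np.array([-2, -1, 0, 1, 2]) * h
            vals = np.array([d.laplace(x) for x in s])
            if n == 0:
                deriv = vals[2]
            elif n == 1:
                deriv = (vals[3] - vals[1]) / (2 * h)
            elif n == 2:
                deriv = (vals[3] - 2 * vals[2] + vals[1]) / h**2
            else:
                deriv = (vals[4] - 2 * vals[3] + 2 * vals[1] - vals[0]) / (2 * h**3)
            assert c[n] * math.factorial(n) == pytest.approx(deriv, rel=1e-4, abs=1e-6)

    def test_order_too_small_rejected(self):
        cwt = make_fixture_chain("two_state")
        with pytest.raises(ValueError):
            transform_table(cwt, order=1)


class TestStationaryOccupancy:
    def test_two_state_exponential(self):
        cwt = make_fixture_chain("two_state", {"k12": 1.0, "k21": 2.0})
        pi = stationary_occupancy(cwt)
        assert pi == pytest.approx([2 / 3, 1 / 3], rel=1e-10)

    def test_symmetric_two_state_ge(self):
        d = GEDist(3.0, 2.0)
        td = lambda: TransitionDensity(d.pdf, d.quantile(1 - 1e-13), alpha=d.a - 1,
                                       scales=(d.quantile(0.5),))
        cwt = ConditionedWaitingTimes(2, {(0, 1): td(), (1, 0): td()})
        assert stationary_occupancy(cwt) == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_markov_limit_across_random_chains(self):
        rng = np.random.default_rng(42)
        for N in (3, 4, 5, 6):
            Q = np.zeros((N, N))
            for i in range(N):
                for j in range(N):
                    if i != j and rng.random() < 0.7:
                        Q[i, j] = rng.uniform(0.2, 5.0)
                # guarantee irreducibility via a cycle
                Q[i, (i + 1) % N] = max(Q[i, (i + 1) % N], rng.uniform(0.2, 1.0))
            np.fill_diagonal(Q, -Q.sum(axis=1))
            cwt = conditioned_from_rates(Q)
            assert stationary_occupancy(cwt) == pytest.approx(
                ctmc_stationary(Q), rel=1e-6, abs=1e-12
            )

    def test_tetrahedron_ground_state_dominates(self):
        chain = ChainModel(4, tuple([ExponentialDist(0.05)] + [GEDist(0.29, 0.56)] * 3),
                           GEDist(5.0, 50.0))
        pi = stationary_occupancy(build_conditioned_waiting_times(chain))
        assert pi[0] > 0.9
        assert np.all(pi[0] > pi[1:])
        assert pi[4] == np.min(pi[1:])

    def test_reducible_chain_reported(self):
        d = ExponentialDist(1.0)
        td = TransitionDensity(d.pdf, 30.0, exp_params=(1.0, 1.0))
        cwt = ConditionedWaitingTimes(3, {(0, 1): td, (1, 0): td, (2, 0): td})
        with pytest.raises(ChainTopologyError):
            stationary_occupancy(cwt)


class TestFPTMoments:
    def test_single_exponential_stage(self):
        k = 3.0
        cwt = conditioned_from_rates(np.array([[-k, k], [k, -k]]))
        f = fpt_moments(cwt, 0, 1)
        assert f.mean == pytest.approx(1 / k, rel=1e-12)
        assert f.cv == pytest.approx(1.0, rel=1e-10)
        assert f.skewness == pytest.approx(2.0, rel=1e-9)
        assert f.excess_kurtosis == pytest.approx(6.0, rel=1e-9)

    def test_erlang_two_stages(self):
        cwt = make_fixture_chain("erlang", {"n_stages": 2, "rate": 4.0})
        f = fpt_moments(cwt, 0, 2)
        assert f.mean == pytest.approx(0.5, rel=1e-12)
        assert f.cv == pytest.approx(1 / math.sqrt(2), rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_birth_death_matches_fundamental_matrix(self, seed):
        rng = np.random.default_rng(seed)
        kp, ko, kc = rng.uniform(0.05, 2.0), rng.uniform(1.0, 20.0), rng.uniform(1.0, 20.0)
        Q = birth_death_generator(kp, ko, kc)
        chain = ChainModel(4, tuple([ExponentialDist(kp)] + [ExponentialDist(ko)] * 3),
                           ExponentialDist(kc))
        f = fpt_moments(build_conditioned_waiting_times(chain), 0, 4)
        oracle = ctmc_fpt_raw_moments(Q, 0, 4)
        for n in range(1, 5):
            assert f.raw_moments[n] == pytest.approx(oracle[n], rel=1e-6)

    def test_general_topology_matches_oracle(self):
        rng = np.random.default_rng(7)
        n = 5
        Q = rng.uniform(0.1, 3.0, (n, n))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        cwt = conditioned_from_rates(Q)
        f = fpt_moments(cwt, 0, n - 1)
        oracle = ctmc_fpt_raw_moments(Q, 0, n - 1)
        for k in range(1, 5):
            assert f.raw_moments[k] == pytest.approx(oracle[k], rel=1e-6)

    def test_exponential_limit_of_slow_driving(self):
        """Slow 0 -> 1 input makes the ISI exponential: cv 1, skew 2, kurt 6."""
        chain = ChainModel(4, tuple([ExponentialDist(1e-4)] + [GEDist(2.0, 5.0)] * 3),
                           GEDist(5.0, 50.0))
        f = fpt_moments(build_conditioned_waiting_times(chain), 0, 4)
        assert f.cv == pytest.approx(1.0, rel=1e-3)
        assert f.skewness == pytest.approx(2.0, rel=1e-3)
        assert f.excess_kurtosis == pytest.approx(6.0, rel=1e-3)

    def test_unreachable_target_raises(self):
        d = ExponentialDist(1.0)
        td = lambda r, R: TransitionDensity(d.pdf, 30.0, exp_params=(r, R))
        # state 1 only goes back to 0: state 2 unreachable
        cwt = ConditionedWaitingTimes(3, {(0, 1): td(1, 1), (1, 0): td(1, 1)})
        with pytest.raises(ChainTopologyError):
            fpt_moments(cwt, 0, 2)


class TestSplittingProbability:
    def _uniform_cwt(self, p=0.5, n=5):
        d = ExponentialDist(1.0)
        trans = {}
        for i in range(1, n - 1):
            trans[(i, i + 1)] = TransitionDensity(d.pdf, 30.0, exp_params=(p, 1.0))
            trans[(i, i - 1)] = TransitionDensity(d.pdf, 30.0, exp_params=(1 - p, 1.0))
        trans[(0, 1)] = TransitionDensity(d.pdf, 30.0, exp_params=(1.0, 1.0))
        trans[(n - 1, n - 2)] = TransitionDensity(d.pdf, 30.0, exp_params=(1.0, 1.0))
        return ConditionedWaitingTimes(n, trans)

    def test_fair_walk_from_one(self):
        assert splitting_probability(self._uniform_cwt(0.5), 1, 4, 0) == pytest.approx(0.25)

    def test_certain_ascent(self):
        cwt = self._uniform_cwt(1.0 - 1e-15)
        assert splitting_probability(cwt, 1, 4, 0) == pytest.approx(1.0)

    def test_matches_monte_carlo_walk(self):
        p_vec = (0.7, 0.8, 0.9)
        d = ExponentialDist(1.0)
        trans = {(0, 1): TransitionDensity(d.pdf, 30.0, exp_params=(1.0, 1.0)),
                 (4, 3): TransitionDensity(d.pdf, 30.0, exp_params=(1.0, 1.0))}
        for i, p in enumerate(p_vec, start=1):
            trans[(i, i + 1)] = TransitionDensity(d.pdf, 30.0, exp_params=(p, 1.0))
            trans[(i, i - 1)] = TransitionDensity(d.pdf, 30.0, exp_params=(1 - p, 1.0))
        cwt = ConditionedWaitingTimes(5, trans)
        analytic = splitting_probability(cwt, 1, 4, 0)

        rng = np.random.default_rng(0)
        n_runs = 200_000
        state = np.ones(n_runs, dtype=int)
        done_up = np.zeros(n_runs, dtype=bool)
        active = np.ones(n_runs, dtype=bool)
        pv = np.array([0.0, *p_vec, 0.0])
        while active.any():
            u = rng.random(active.sum())
            s = state[active]
            s = np.where(u < pv[s], s + 1, s - 1)
            state[active] = s
            hit_up = active.copy()
            hit_up[active] = s == 4
            done_up |= hit_up
            still = active.copy()
            still[active] = (s != 4) & (s != 0)
            active = still
        mc = done_up.mean()
        se = math.sqrt(mc * (1 - mc) / n_runs)
        assert abs(analytic - mc) < 3 * se

    def test_monotone_in_one_step_weights(self):
        vals = [splitting_probability(self._uniform_cwt(p), 1, 4, 0)
                for p in (0.3, 0.4, 0.5, 0.6, 0.7)]
        assert np.all(np.diff(vals) > 0)

    def test_requires_interior_start(self):
        with pytest.raises(ValueError):
            splitting_probability(self._uniform_cwt(), 0, 4, 0)
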