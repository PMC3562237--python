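import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
import scipy.stats
from hypothesis import given, strategies as st

from grm import (
    RecruitmentNetwork,
    Shortcut,
    StateDistribution,
    add_reversible,
    add_shortcuts,
    build_sr,
    clockwork_propagate,
    embedded_jump_probability,
    embedded_transition_matrix,
    expand_substeps,
    generator_matrix,
    landmark_waiting_time_pdf,
    master_equation_rhs,
    propagate,
    sample_ensemble,
    sample_trajectory,
    stationary_distribution,
)
from grm.dynamics import landmark_marginal

from conftest import pooled_chisquare


def delta(n, k=0):
    p = np.zeros(n)
    p[k] = 1.0
    return StateDistribution(probs=p)


class TestMasterEquationRHS:
    def test_uniform_is_stationary_on_cycle(self, sr20):
        dp = master_equation_rhs(sr20, StateDistribution(np.full(20, 0.05)))
        assert np.allclose(dp, 0.0, atol=1e-15)

    def test_single_edge_flow(self):
        net = build_sr(2, 1.0)
        dp = master_equation_rhs(net, delta(2))
        assert np.allclose(dp, [-1.0, 1.0])

    def test_matches_dense_generator_oracle(self, random_net30):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(30))
        dp = master_equation_rhs(random_net30, StateDistribution(p))
        oracle = generator_matrix(random_net30).T @ p
        assert np.allclose(dp, oracle, atol=1e-14)
        assert abs(dp.sum()) < 1e-12  # conservation

    def test_size_mismatch(self, sr20):
        with pytest.raises(ValueError):
            master_equation_rhs(sr20, delta(5))


class TestPropagate:
    def test_time_zero_returns_initial(self, sr20):
        d0 = delta(20, 3)
        out = propagate(sr20, d0, np.array([0.0]))
        assert np.allclose(out[0].probs, d0.probs)

    def test_two_state_closed_form(self):
        # symmetric 2-state switch, delta start: p0(t) = (1 + exp(-2t)) / 2
        net = RecruitmentNetwork(2, np.array([[0.0, 1.0], [1.0, 0.0]]))
        grid = np.linspace(0.0, 3.0, 13)
        out = propagate(net, delta(2), grid)
        expected = 0.5 * (1 + np.exp(-2 * grid))
        got = np.array([d.probs[0] for d in out])
        assert np.allclose(got, expected, atol=1e-7)

    @pytest.mark.parametrize("method", ["bdf", "expm"])
    def test_matches_dense_matrix_exponential(self, random_net30, method):
        rng = np.random.default_rng(1)
        p0 = rng.dirichlet(np.ones(30))
        grid = np.linspace(0.0, 10.0, 11)
        out = propagate(random_net30, StateDistribution(p0), grid, method=method)
        qt = generator_matrix(random_net30).T
        for d, t in zip(out, grid):
            assert np.max(np.abs(d.probs - scipy.linalg.expm(qt * t) @ p0)) < 1e-6

    def test_conservation_and_nonnegativity(self, sr20):
        out = propagate(sr20, delta(20), np.linspace(0, 40, 81))
        for d in out:
            assert abs(d.probs.sum() - 1.0) < 1e-7
            assert d.probs.min() >= 0.0

    def test_decreasing_grid_rejected(self, sr20):
        with pytest.raises(ValueError):
            propagate(sr20, delta(20), np.array([1.0, 0.5]))


class TestStationary:
    def test_uniform_on_constant_rate_cycle(self):
        for n in (5, 50):
            pi = stationary_distribution(build_sr(n, 2.0))
            assert np.allclose(pi.probs, 1.0 / n, atol=1e-12)

    def test_flux_balance_with_one_fast_edge(self):
        # doubling one edge's rate halves its source state's occupancy
        rates = np.array(build_sr(10, 1.0).rates)
        rates[4, 5] = 2.0
        pi = stationary_distribution(RecruitmentNetwork(10, rates)).probs
        assert pi[4] == pytest.approx(pi[0] / 2, rel=1e-9)

    def test_matches_long_time_propagation_with_shortcut(self, sr20):
        net = add_shortcuts(sr20, [Shortcut(15, 5, 0.5)])
        pi = stationary_distribution(net)
        out = propagate(net, delta(20), np.array([0.0, 2000.0]), method="expm")
        assert np.max(np.abs(out[-1].probs - pi.probs)) < 1e-6

    def test_reducible_network_reports_components(self):
        rates = np.zeros((4, 4))
        rates[0, 1] = rates[1, 0] = 1.0
        rates[2, 3] = rates[3, 2] = 1.0
        with pytest.raises(ValueError, match="components"):
            stationary_distribution(RecruitmentNetwork(4, rates))


class TestSampling:
    def test_trajectory_reproducible_and_valid(self, sr20):
        t1 = sample_trajectory(sr20, 0, 50.0, seed=7)
        t2 = sample_trajectory(sr20, 0, 50.0, seed=7)
        assert np.array_equal(t1.jump_times, t2.jump_times)
        assert np.array_equal(t1.states, t2.states)
        assert np.all(np.diff(t1.jump_times) > 0)
        # consecutive states connected by a positive-rate edge
        for a, b in zip(t1.states[:-1], t1.states[1:]):
            assert sr20.rates[a, b] > 0

    def test_mean_cycle_completion_time(self):
        # one lap of the N=200 unit-rate cycle is a sum of 200 unit
        # exponentials: mean 200, sd sqrt(200)
        net = build_sr(200, 1.0)
        n_traj = 400
        laps = []
        for k in range(n_traj):
            tr = sample_trajectory(net, 0, 350.0, seed=1000 + k)
            assert len(tr.jump_times) >= 200
            laps.append(tr.jump_times[199])
        band = 4 * np.sqrt(200 / n_traj)
        assert abs(np.mean(laps) - 200.0) < band

    def test_ensemble_marginals_match_master_equation(self, sr20):
        nets = {
            "sr": sr20,
            "shortcut": add_shortcuts(sr20, [Shortcut(15, 5, 0.5)]),
            "reversible": add_reversible(sr20, 0.3),
        }
        for label, net in nets.items():
            t_obs = 7.0
            p = propagate(net, delta(20), np.array([0.0, t_obs]), method="expm")[-1].probs
            finals = sample_ensemble(net, 0, t_obs, 100_000, seed=11)
            counts = np.bincount(finals, minlength=20)
            _, pval = pooled_chisquare(counts, 100_000 * p)
            assert pval > 0.01, f"{label}: chi-square rejected (p={pval})"

    def test_invalid_t_max(self, sr20):
        with pytest.raises(ValueError):
            sample_trajectory(sr20, 0, 0.0, seed=0)


class TestWaitingTimes:
    def test_m1_is_exponential(self):
        t = np.linspace(0, 5, 50)
        assert np.allclose(landmark_waiting_time_pdf(1.0, 1, t), np.exp(-t))

    @pytest.mark.parametrize("m,rate", [(1, 1.0), (7, 2.0), (400, 0.5)])
    def test_mean_is_inverse_rate(self, m, rate):
        mean = scipy.integrate.quad(
            lambda t: t * landmark_waiting_time_pdf(rate, m, t),
            0, 30 / rate, points=[1 / rate], limit=200,
        )[0]
        assert mean == pytest.approx(1 / rate, rel=1e-6)

    def test_clockwork_concentration_at_large_m(self):
        # m=400: 99% of the mass within 15% of the deterministic transit time
        mass = scipy.stats.gamma(a=400, scale=1 / 400).cdf(1.15) - \
            scipy.stats.gamma(a=400, scale=1 / 400).cdf(0.85)
        got = scipy.integrate.quad(
            lambda t: landmark_waiting_time_pdf(1.0, 400, t), 0.85, 1.15
        )[0]
        assert got == pytest.approx(mass, rel=1e-9)
        assert got > 0.99

    def test_variance_scales_inversely_with_substeps(self):
        # numerical moments of the implemented density; log-log slope -1
        variances = []
        ms = [10, 100, 1000]
        for m in ms:
            mean = scipy.integrate.quad(
                lambda t: t * landmark_waiting_time_pdf(1.0, m, t),
                0, 5, points=[1.0], limit=400,
            )[0]
            m2 = scipy.integrate.quad(
                lambda t: t * t * landmark_waiting_time_pdf(1.0, m, t),
                0, 5, points=[1.0], limit=400,
            )[0]
            variances.append(m2 - mean**2)
        slope = np.polyfit(np.log(ms), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_erlang_law_on_expanded_network(self):
        # landmark passage times sampled from the m-substep expansion follow
        # the Erlang(m, m*rate) law
        m = 20
        big = expand_substeps(build_sr(5, 1.0), m)
        traj = sample_trajectory(big, 0, 1500.0, seed=17)
        landmark = traj.states // m
        cross = traj.jump_times[np.flatnonzero(np.diff(landmark) != 0)]
        waits = np.diff(cross)
        assert waits.size > 1000
        _, pval = scipy.stats.kstest(waits, scipy.stats.gamma(a=m, scale=1 / m).cdf)
        assert pval > 0.01


class TestEmbeddedChain:
    def test_single_edge_probability_one(self, sr20):
        assert embedded_jump_probability(sr20, 0, 1) == 1.0

    def test_equal_rates_half(self, sr20):
        net = add_shortcuts(sr20, [Shortcut(0, 10, 1.0)])
        assert embedded_jump_probability(net, 0, 10) == pytest.approx(0.5)

    def test_matches_sampled_jump_frequencies(self):
        # rates 1 (forward) and 3 (shortcut): shortcut wins 75% of exits
        net = add_shortcuts(build_sr(3, 1.0), [Shortcut(0, 2, 3.0)])
        assert embedded_jump_probability(net, 0, 2) == pytest.approx(0.75)
        traj = sample_trajectory(net, 0, 6000.0, seed=5)
        pairs = np.column_stack([traj.states[:-1], traj.states[1:]])
        exits = pairs[pairs[:, 0] == 0]
        n, k = exits.shape[0], int((exits[:, 1] == 2).sum())
        assert n > 3000
        phat = k / n
        assert abs(phat - 0.75) < 4 * np.sqrt(0.75 * 0.25 / n)

    def test_missing_edge_rejected(self, sr20):
        with pytest.raises(ValueError):
            embedded_jump_probability(sr20, 0, 5)

    def test_rows_sum_to_one(self, random_net30):
        t = embedded_transition_matrix(random_net30)
        assert np.allclose(t.sum(axis=1), 1.0)


class TestClockwork:
    def test_sr_clockwork_is_exact_rotation(self, sr20):
        rng = np.random.default_rng(2)
        p0 = rng.dirichlet(np.ones(20))
        _, dists = clockwork_propagate(sr20, StateDistribution(p0), 20)
        assert np.allclose(dists[7].probs, np.roll(p0, 7))
        assert np.allclose(dists[20].probs, p0)  # full period

    def test_conservation(self, sr20):
        net = add_shortcuts(sr20, [Shortcut(15, 5, 0.5)])
        _, dists = clockwork_propagate(net, delta_dist(20), 100)
        for d in dists:
            assert abs(d.probs.sum() - 1.0) < 1e-12

    def test_requires_uniform_forward_rate(self):
        rates = np.array(build_sr(5, 1.0).rates)
        rates[2, 3] = 2.0
        with pytest.raises(ValueError, match="uniform"):
            clockwork_propagate(RecruitmentNetwork(5, rates), delta_dist(5), 3)


def delta_dist(n, k=0):
    p = np.zeros(n)
    p[k] = 1.0
    return StateDistribution(probs=p)


class TestSubstepExpansion:
    def test_m1_identity(self, sr20):
        assert expand_substeps(sr20, 1) is sr20

    def test_expanded_size_and_rates(self):
        big = expand_substeps(build_sr(4, 2.0), 3)
        assert big.n_states == 12
        # per-substep rate is m * lambda, preserving the mean transit time
        assert big.rates[0, 1] == pytest.approx(6.0)
        assert big.rates[2, 3] == pytest.approx(6.0)  # wraps into next landmark chain

    def test_landmark_marginal_aggregation(self):
        big = expand_substeps(build_sr(4, 1.0), 3)
        p = np.full(12, 1 / 12)
        marg = landmark_marginal(StateDistribution(p), 4)
        assert np.allclose(marg, 0.25)


@given(seed=st.integers(0, 2**16), n=st.integers(3, 15))
def test_propagation_preserves_simplex(seed, n):
    """Any random network keeps distributions on the simplex."""
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0, 2, (n, n)) * (rng.random((n, n)) < 0.4)
    np.fill_diagonal(rates, 0)
    rates[np.arange(n), (np.arange(n) + 1) % n] += 0.5
    net = RecruitmentNetwork(n, rates)
    p0 = rng.dirichlet(np.ones(n))
    out = propagate(net, StateDistribution(p0), np.linspace(0, 5, 6), method="expm")
    for d in out:
        assert abs(d.probs.sum() - 1.0) < 1e-9
        assert d.probs.min() >= 0
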