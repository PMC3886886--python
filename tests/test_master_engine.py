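import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leakynet import (
    CountState,
    LatticeDistribution,
    LatticeStateSpace,
    bd_stationary_closedform,
    build_generator,
    max_abs_affinity,
    mean_first_passage,
    solve_stationary,
    solve_transient,
    state_exit_time,
    stationary_of,
)
from leakynet.master_engine import (
    ReducibleChainError,
    StateSpaceCapError,
    lattice_propensities,
)
from leakynet.model_core import coarse_propensities

from conftest import make_single_block, make_two_block, sisa_small


class TestLatticeStateSpace:
    def test_bijection(self):
        space = LatticeStateSpace([3, 2])
        for i in range(space.cardinality):
            assert space.index_of(space.state_of(i)) == i

    def test_enumeration_order_first_coordinate_fastest(self):
        space = LatticeStateSpace([2, 1])
        states = space.all_states()
        assert states[:4].tolist() == [[0, 0], [1, 0], [2, 0], [0, 1]]

    def test_cardinality(self):
        assert LatticeStateSpace([3, 2]).cardinality == 12


class TestBuildGenerator:
    def test_two_state(self, two_state):
        Q = build_generator(two_state).toarray()
        np.testing.assert_allclose(Q, [[-1.0, 1.0], [3.0, -3.0]])

    def test_sisa_n2_tridiagonal(self):
        m = sisa_small(2)
        Q = build_generator(m).toarray()
        expected = np.zeros((3, 3))
        for n in range(3):
            beta, delta = coarse_propensities(m, [n])
            if n < 2:
                expected[n, n + 1] = beta[0]
            if n > 0:
                expected[n, n - 1] = delta[0]
        np.fill_diagonal(expected, -expected.sum(axis=1))
        np.testing.assert_allclose(Q, expected)

    def test_row_sums_zero(self):
        m = make_two_block([3, 2], [0.5, 0.2], [0.3, 0.4],
                           [[0.1, -0.2], [0.3, 0.0]], gain_on="tanh_plus")
        Q = build_generator(m)
        rows = np.asarray(Q.sum(axis=1)).ravel()
        assert np.abs(rows).max() <= 1e-12 * np.abs(Q.data).max()

    def test_cap(self):
        m = make_single_block(100, 0.1, 0.1)
        with pytest.raises(StateSpaceCapError, match="resize"):
            build_generator(m, cap=50)

    def test_irreducibility_check(self, two_state):
        build_generator(two_state, check_irreducible=True)


class TestSolveTransient:
    def test_t0_identity(self, two_state):
        Q = build_generator(two_state)
        space = LatticeStateSpace.of(two_state)
        p0 = LatticeDistribution.point_mass(space, [0])
        (out,) = solve_transient(Q, p0, [0.0])
        np.testing.assert_allclose(out.p, p0.p)

    def test_two_state_closed_form(self, two_state):
        # relaxation from delta at 0: p1(t) = 0.25 (1 - exp(-4t))
        Q = build_generator(two_state)
        space = LatticeStateSpace.of(two_state)
        p0 = LatticeDistribution.point_mass(space, [0])
        times = [0.1, 0.5, 1.0, 3.0]
        sols = solve_transient(Q, p0, times)
        for t, sol in zip(times, sols):
            assert sol.p[1] == pytest.approx(0.25 * (1 - np.exp(-4 * t)),
                                             abs=1e-7)

    def test_ergodic_limit(self, two_state):
        Q = build_generator(two_state)
        space = LatticeStateSpace.of(two_state)
        p0 = LatticeDistribution.point_mass(space, [0])
        (late,) = solve_transient(Q, p0, [50.0])
        pi = solve_stationary(Q, space)
        assert late.total_variation(pi) <= 1e-6

    def test_mass_conserved(self):
        m = sisa_small(20)
        Q = build_generator(m)
        space = LatticeStateSpace.of(m)
        p0 = LatticeDistribution.point_mass(space, [0])
        for sol in solve_transient(Q, p0, [1.0, 10.0, 100.0]):
            assert abs(sol.p.sum() - 1.0) <= 1e-8


class TestSolveStationary:
    def test_two_state(self, two_state):
        pi = solve_stationary(build_generator(two_state))
        np.testing.assert_allclose(pi.p, [0.75, 0.25], atol=1e-12)

    def test_binomial_product_form(self):
        # leak-only: independent nodes, Binomial(N, a/(a+b))
        from scipy.stats import binom

        m = make_single_block(12, 0.4, 0.6)
        pi = stationary_of(m)
        expected = binom.pmf(np.arange(13), 12, 0.4)
        assert 0.5 * np.abs(pi.p - expected).sum() <= 1e-9

    def test_matches_bd_closedform_sisa(self):
        m = sisa_small(30)
        pi = stationary_of(m)
        _, beta, delta = lattice_propensities(m)
        oracle = bd_stationary_closedform(beta[:-1, 0], delta[1:, 0])
        assert pi.total_variation(oracle) <= 1e-9

    def test_reducible_rejected(self):
        # a=0: origin absorbing (classical SIS), not leaky
        from leakynet import SISaParams, build_sisa

        m = build_sisa(SISaParams(0.0, 0.2, 0.05, N0=10.0, omega=1.0))
        with pytest.raises(ReducibleChainError):
            solve_stationary(build_generator(m))


class TestBdClosedForm:
    def test_symmetric_walk_uniform(self):
        pi = bd_stationary_closedform([1.0] * 5, [1.0] * 5)
        np.testing.assert_allclose(pi.p, np.full(6, 1 / 6))

    def test_two_state(self):
        pi = bd_stationary_closedform([1.0], [3.0])
        np.testing.assert_allclose(pi.p, [0.75, 0.25])

    def test_binomial_half(self):
        pi = bd_stationary_closedform([2.0, 1.0], [1.0, 2.0])
        np.testing.assert_allclose(pi.p, [0.25, 0.5, 0.25])

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bd_stationary_closedform([0.0], [1.0])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 32 - 1))
def test_oracle_equivalence_random_models(seed):
    """solve_stationary == birth-death closed form on random 1-D models."""
    rng = np.random.default_rng(seed)
    N = int(rng.integers(2, 25))
    m = make_single_block(N, rng.uniform(0.05, 2.0), rng.uniform(0.05, 2.0),
                          weight=rng.uniform(0.0, 1.0), h=rng.uniform(0, 0.3),
                          gain_on="tanh_plus")
    pi = stationary_of(m)
    _, beta, delta = lattice_propensities(m)
    oracle = bd_stationary_closedform(beta[:-1, 0], delta[1:, 0])
    assert pi.total_variation(oracle) <= 1e-9


class TestMeanFirstPassage:
    def test_start_in_target(self, two_state):
        Q = build_generator(two_state)
        space = LatticeStateSpace.of(two_state)
        assert mean_first_passage(Q, space, [0], [[0]]) == 0.0

    def test_two_state_holding_time(self, two_state):
        Q = build_generator(two_state)
        space = LatticeStateSpace.of(two_state)
        assert mean_first_passage(Q, space, [0], [[1]]) == pytest.approx(1.0)

    def test_three_state_formula(self):
        # birth-death 0-1-2: tau_0 = 1/l0 + 1/l1 + m1/(l0 l1)
        m = make_single_block(2, 0.7, 1.3)
        _, beta, delta = lattice_propensities(m)
        l0, l1 = beta[0, 0], beta[1, 0]
        m1 = delta[1, 0]
        Q = build_generator(m)
        space = LatticeStateSpace.of(m)
        tau = mean_first_passage(Q, space, [0], [[2]])
        assert tau == pytest.approx(1 / l0 + 1 / l1 + m1 / (l0 * l1),
                                    rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_against_dense_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = make_two_block(rng.integers(2, 6, 2), rng.uniform(0.1, 1, 2),
                           rng.uniform(0.1, 1, 2),
                           rng.uniform(-0.3, 0.5, (2, 2)),
                           gain_on="tanh_plus")
        Q = build_generator(m)
        space = LatticeStateSpace.of(m)
        target_state = space.sizes.copy()
        tau = mean_first_passage(Q, space, [0, 0], [target_state])
        # dense brute force
        dense = Q.toarray()
        tgt = space.index_of(target_state)
        keep = [i for i in range(space.cardinality) if i != tgt]
        sub = dense[np.ix_(keep, keep)]
        tau_all = np.linalg.solve(sub, -np.ones(len(keep)))
        assert tau == pytest.approx(tau_all[keep.index(0)], rel=1e-10)


class TestStateExitTime:
    def test_sisa_origin_inverse_Na(self):
        from leakynet import SISaParams, build_sisa

        m = build_sisa(SISaParams(1e-4, 0.107, 0.0566186093028184,
                                  N0=200.0, omega=0.25))
        assert m.sizes[0] == 50
        assert state_exit_time(m, [0]) == pytest.approx(200.0)

    def test_two_state_active(self, two_state):
        assert state_exit_time(two_state, [1]) == pytest.approx(1 / 3)

    def test_absorbing_is_inf(self):
        from leakynet import SISaParams, build_sisa

        m = build_sisa(SISaParams(0.0, 0.2, 0.05, N0=10.0, omega=1.0))
        assert state_exit_time(m, [0]) == np.inf


class TestMaxAbsAffinity:
    def test_bd_stationary_detailed_balance(self):
        m = sisa_small(25)
        Q = build_generator(m)
        pi = stationary_of(m)
        assert max_abs_affinity(Q, pi) <= 1e-8

    def test_asymmetric_2d_positive(self):
        # cyclic probability flux on a 2-D lattice breaks detailed balance
        m = make_two_block([2, 2], [0.3, 0.6], [0.5, 0.2],
                           [[0.0, 0.8], [-0.6, 0.0]], gain_on="tanh_plus")
        Q = build_generator(m)
        pi = solve_stationary(Q, LatticeStateSpace.of(m))
        assert max_abs_affinity(Q, pi) > 1e-3

    def test_transient_affinity_decays_to_stationary_level(self):
        m = sisa_small(10)
        Q = build_generator(m)
        space = LatticeStateSpace.of(m)
        pi = solve_stationary(Q, space)
        p0 = LatticeDistribution(
            space, np.full(space.cardinality, 1 / space.cardinality), time=0.0)
        early, late = solve_transient(Q, p0, [0.5, 2000.0])
        a_early = max_abs_affinity(Q, early)
        a_late = max_abs_affinity(Q, late)
        assert a_early > a_late
        assert a_late <= max_abs_affinity(Q, pi) + 1e-3


class TestDistributionIO:
    def test_tsv_round_trip(self, tmp_path):
        m = make_two_block([2, 3], [0.4, 0.3], [0.2, 0.5],
                           np.zeros((2, 2)))
        pi = stationary_of(m)
        path = tmp_path / "dist.tsv"
        pi.to_tsv(path)
        back = LatticeDistribution.from_tsv(path)
        assert back.total_variation(pi) <= 1e-12
        assert back.omega == pi.omega
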