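import numpy as np
import pytest

from leakynet import (
    bin_avalanches,
    build_sisa,
    default_sisa_params,
    detect_threshold_avalanches,
    fit_size_distribution,
    resize,
    shape_collapse,
    simulate,
    size_duration_scaling,
    synth_selfsimilar_avalanches,
)
from leakynet.avalanche_stats import AvalancheCatalog, Avalanche, rsq_vs_omega
from leakynet.gillespie import EventTrajectory


def hand_trajectory(times, directions, t_end, n_blocks=1):
    times = np.asarray(times, dtype=float)
    return EventTrajectory(
        model_hash="test", initial=np.zeros(n_blocks, dtype=np.int64),
        times=times,
        blocks=np.zeros(times.size, dtype=np.int16),
        directions=np.asarray(directions, dtype=np.int8),
        t_end=float(t_end), seed=0)


class TestThresholdDetector:
    def test_never_reaching_threshold(self):
        m = resize(build_sisa(default_sisa_params()), 0.5)  # N=100
        traj = hand_trajectory([], [], 10.0)
        cat = detect_threshold_avalanches(traj, m, 0.5)
        assert cat.count == 0 and cat.rate == 0.0

    def test_hand_trace_two_avalanches(self):
        # N=100, theta=0.01: active whenever >= 1 node is on
        m = resize(build_sisa(default_sisa_params()), 0.5)
        traj = hand_trajectory([1.0, 2.5, 5.0, 5.5, 6.0, 7.0],
                               [1, -1, 1, 1, -1, -1], 10.0)
        cat = detect_threshold_avalanches(traj, m, 0.01)
        assert cat.count == 2
        sizes = cat.fractional_sizes
        np.testing.assert_allclose(sizes, [0.01, 0.02])
        np.testing.assert_allclose(cat.durations, [1.5, 2.0])

    def test_rate(self):
        cat = AvalancheCatalog(
            threshold=0.1,
            avalanches=[Avalanche(0, 1, 1, 0.1), Avalanche(2, 3, 1, 0.1)],
            span=10.0, time_unit="day")
        assert cat.rate == pytest.approx(0.2)

    def test_theta_out_of_range(self):
        m = resize(build_sisa(default_sisa_params()), 0.5)
        traj = hand_trajectory([], [], 1.0)
        with pytest.raises(ValueError, match="theta"):
            detect_threshold_avalanches(traj, m, 0.0)

    def test_activation_conservation(self):
        # total +1 events = sum of catalog counts + activations outside
        m = resize(build_sisa(default_sisa_params()), 0.1)
        traj = simulate(m, 20000.0, seed=5)
        cat = detect_threshold_avalanches(traj, m, 0.05)
        total_plus = int((traj.directions == 1).sum())
        inside = sum(a.activation_count for a in cat.avalanches)
        starts = np.array([a.start for a in cat.avalanches])
        ends = np.array([a.end for a in cat.avalanches])
        acts = traj.times[traj.directions == 1]
        outside = sum(
            1 for t in acts
            if not np.any((starts <= t) & (t < ends))
        )
        assert inside + outside == total_plus

    def test_smaller_theta_merges_never_splits(self):
        m = resize(build_sisa(default_sisa_params()), 0.1)
        traj = simulate(m, 50000.0, seed=8)
        big = detect_threshold_avalanches(traj, m, 0.10)
        small = detect_threshold_avalanches(traj, m, 0.05)
        # every theta-big avalanche lies inside some theta-small one
        for a in big.avalanches:
            assert any(b.start <= a.start and a.end <= b.end
                       for b in small.avalanches)


class TestFitSizeDistribution:
    @staticmethod
    def catalog_from_sizes(frac_sizes, theta=0.01):
        avs = [Avalanche(float(i), float(i) + 0.5, max(1, int(s * 100)), s)
               for i, s in enumerate(frac_sizes)]
        return AvalancheCatalog(threshold=theta, avalanches=avs,
                                span=float(len(avs)))

    def test_exact_power_law_grid(self):
        # density ~ s^-1.5 realized exactly on log-bin centers
        edges = np.logspace(-2, 0, 41)
        centers = np.sqrt(edges[:-1] * edges[1:])
        widths = np.diff(edges)
        counts = np.rint(3e3 * centers ** -1.5 * widths).astype(int)
        sizes = np.repeat(centers, counts)
        cat = self.catalog_from_sizes(sizes)
        fit = fit_size_distribution(cat, bins_per_decade=20)
        assert fit.slope == pytest.approx(-1.5, abs=2e-3)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-4)

    def test_exponential_sizes_fit_worse(self):
        rng = np.random.default_rng(0)
        power = 0.01 * (1 - rng.uniform(size=4000)) ** (-1 / 0.5)
        power = power[power < 1.0]
        expo = rng.exponential(0.05, size=4000) + 0.01
        expo = expo[expo < 1.0]
        fit_p = fit_size_distribution(self.catalog_from_sizes(power))
        fit_e = fit_size_distribution(self.catalog_from_sizes(expo))
        assert fit_p.adj_r_squared > fit_e.adj_r_squared + 0.05

    def test_too_few_avalanches(self):
        cat = self.catalog_from_sizes([0.1] * 5)
        with pytest.raises(ValueError, match="need"):
            fit_size_distribution(cat)


class TestBinDetector:
    def test_hand_binning(self):
        avset = bin_avalanches([0.5, 1.2, 3.7], 1.0, t_end=5.0)
        assert avset.count == 2
        assert avset.durations.tolist() == [2, 1]
        assert avset.sizes.tolist() == [2, 1]
        assert avset.shapes[0].tolist() == [1, 1]

    def test_all_bins_nonempty_flagged_truncated(self):
        avset = bin_avalanches([0.5, 1.5, 2.5], 1.0, t_end=3.0)
        assert avset.count == 1
        assert bool(avset.truncated[0])

    def test_size_conservation(self):
        rng = np.random.default_rng(4)
        events = np.sort(rng.uniform(0, 1000, 500))
        avset = bin_avalanches(events, 2.0, t_end=1001.0)
        assert int(avset.sizes.sum()) == 500

    def test_empty_events(self):
        avset = bin_avalanches([], 1.0)
        assert avset.count == 0

    def test_bad_delta(self):
        with pytest.raises(ValueError, match="delta"):
            bin_avalanches([1.0], 0.0)

    def test_larger_delta_merges_never_splits(self):
        rng = np.random.default_rng(9)
        events = np.sort(rng.uniform(0, 500, 300))
        fine = bin_avalanches(events, 1.0, t_end=501.0)
        coarse = bin_avalanches(events, 2.0, t_end=501.0)
        assert coarse.count <= fine.count


class TestSizeDurationScaling:
    def test_exact_line(self):
        from leakynet.avalanche_stats import BinnedAvalancheSet

        durations = np.repeat([2, 4, 8, 16], 10)
        sizes = 3.0 * (durations * 1.0) ** 1.5
        avset = BinnedAvalancheSet(
            delta=1.0, durations=durations.astype(np.int64), sizes=sizes,
            shapes=[np.ones(d) for d in durations],
            truncated=np.zeros(durations.size, bool), n_bins=100)
        gamma, diag = size_duration_scaling(avset)
        assert gamma == pytest.approx(1.5, abs=1e-9)
        assert diag["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_generator_exact_with_normalized_sizes(self):
        avset = synth_selfsimilar_avalanches(
            1.5, lambda u: 4 * u * (1 - u), durations=[5, 9, 17, 33],
            counts=20, noise="none", normalize_sizes=True)
        gamma, _ = size_duration_scaling(avset)
        assert gamma == pytest.approx(1.5, abs=1e-9)

    def test_poisson_noise_recovery(self):
        avset = synth_selfsimilar_avalanches(
            1.5, lambda u: 4 * u * (1 - u),
            durations=[4, 6, 9, 13, 19, 28, 42], counts=1500,
            noise="poisson", seed=2, amplitude=20.0, normalize_sizes=True)
        gamma, _ = size_duration_scaling(avset)
        assert gamma == pytest.approx(1.5, abs=0.05)

    def test_insufficient_durations(self):
        avset = synth_selfsimilar_avalanches(
            1.5, lambda u: np.ones_like(u), durations=[4, 8], counts=20,
            noise="none")
        with pytest.raises(ValueError, match="duration groups"):
            size_duration_scaling(avset)


def tent(u):
    return 1.0 - np.abs(2.0 * np.asarray(u) - 1.0)


class TestShapeCollapse:
    def test_exact_self_similarity_zero_error(self):
        # odd bin counts sample the tent's kink exactly, so every
        # duration's pinned polyline reproduces the same function and the
        # collapse error vanishes to machine precision
        avset = synth_selfsimilar_avalanches(
            2.0, tent, durations=[5, 9, 15, 25], counts=3, noise="none")
        res = shape_collapse(avset, 2.0)
        assert res.collapse_error <= 1e-12

    def test_wrong_gamma_strictly_worse(self):
        avset = synth_selfsimilar_avalanches(
            2.0, tent, durations=[5, 9, 15, 25], counts=3, noise="none")
        right = shape_collapse(avset, 2.0).collapse_error
        for wrong in (1.5, 2.5):
            assert shape_collapse(avset, wrong).collapse_error > right + 1e-6

    def test_parabola_near_zero_error(self):
        # quadratic scaling function: exact up to linear-interpolation error
        avset = synth_selfsimilar_avalanches(
            1.5, lambda u: 4 * u * (1 - u), durations=[15, 21, 31],
            counts=2, noise="none")
        res = shape_collapse(avset, 1.5)
        assert res.collapse_error <= 1e-3
        assert shape_collapse(avset, 2.0).collapse_error > res.collapse_error

    def test_symmetric_scaling_fn_symmetric_mean_shapes(self):
        avset = synth_selfsimilar_avalanches(
            1.5, tent, durations=[9, 17], counts=5, noise="none")
        res = shape_collapse(avset, 1.5)
        for shape in res.rescaled_shapes.values():
            np.testing.assert_allclose(shape, shape[::-1], atol=1e-12)

    def test_grid_spans_unit_interval(self):
        avset = synth_selfsimilar_avalanches(
            1.5, tent, durations=[5, 9], counts=2, noise="none")
        res = shape_collapse(avset, 1.5)
        assert res.grid[0] == 0.0 and res.grid[-1] == 1.0
        for shape in res.rescaled_shapes.values():
            assert shape[0] == 0.0 and shape[-1] == 0.0

    def test_needs_two_durations(self):
        avset = synth_selfsimilar_avalanches(
            1.5, tent, durations=[5], counts=2, noise="none")
        with pytest.raises(ValueError, match="2 distinct durations"):
            shape_collapse(avset, 1.5)


class TestPipelineRecovery:
    """bin -> scaling -> collapse recovers the generator's exponent."""

    def test_full_recovery(self):
        gamma_true = 1.5
        avset = synth_selfsimilar_avalanches(
            gamma_true, lambda u: 4 * u * (1 - u),
            durations=[5, 7, 11, 15, 21, 29], counts=2000,
            noise="poisson", seed=7, amplitude=30.0, normalize_sizes=True)
        gamma, _ = size_duration_scaling(avset)
        assert gamma == pytest.approx(gamma_true, abs=0.05)
        err_true = shape_collapse(avset, gamma).collapse_error
        err_hi = shape_collapse(avset, gamma + 0.5).collapse_error
        err_lo = shape_collapse(avset, gamma - 0.5).collapse_error
        assert err_hi > err_true and err_lo > err_true


class TestRsqVsOmega:
    def test_single_point_grid(self):
        m = build_sisa(default_sisa_params())
        df = rsq_vs_omega(m, [0.1], t_end=30000.0, theta=0.01, seed=1)
        assert len(df) == 1
        assert "smoothed" not in df.columns

    def test_polynomial_smoother_tracks_inputs(self):
        # degree-4 fit of a degree-2 sequence is exact
        x = np.linspace(0, 1, 9)
        y = 1.0 - 0.5 * x ** 2
        coeffs = np.polyfit(x, y, 4)
        np.testing.assert_allclose(np.polyval(coeffs, x), y, atol=1e-10)
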