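"""Population traces, expectation values, density projections, branching."""

import numpy as np
import pytest

from terpued.ensemble import (
    S0,
    S1,
    WavepacketEnsemble,
    WeightedTrajectory,
    branching_fraction,
    density_projection_2d,
    expectation,
    population_trace,
)
from terpued.geometry import pair_distance_coordinate, psi_sum_coordinate


def _toy_trajectory(template, times, c3c4_values, states, weight):
    """Trajectory that rigidly translates C4 to realize given C3-C4 distances."""
    i3 = template.carbon_index("C3")
    i4 = template.carbon_index("C4")
    base = template.positions
    direction = base[i4] - base[i3]
    direction = direction / np.linalg.norm(direction)
    frames = []
    for r in c3c4_values:
        pos = base.copy()
        pos[i4] = pos[i3] + r * direction
        frames.append(pos)
    return WeightedTrajectory(
        times=np.asarray(times, float),
        positions=np.stack(frames),
        states=np.asarray(states, np.int8),
        weights=np.full(len(times), weight),
        template=template,
    )


@pytest.fixture
def two_traj_ensemble(reactant):
    times = [0.0, 10.0, 20.0]
    t1 = _toy_trajectory(reactant, times, [1.5, 1.5, 1.5], [S1, S0, S0], 0.25)
    t2 = _toy_trajectory(reactant, times, [1.5, 2.0, 3.0], [S1, S1, S0], 0.75)
    return WavepacketEnsemble([t1, t2], np.asarray(times))


class TestPopulation:
    def test_all_start_in_s1(self, two_traj_ensemble):
        assert population_trace(two_traj_ensemble, S1)[0] == pytest.approx(1.0)

    def test_complement_identity(self, small_ensemble):
        s0 = population_trace(small_ensemble, S0)
        s1 = population_trace(small_ensemble, S1)
        np.testing.assert_allclose(s0 + s1, 1.0, atol=1e-12)

    def test_hop_times_match_empirical_cdf(self):
        """S0 population equals the empirical CDF of configured hop times."""
        from terpued.surrogate import SurrogateParams, generate_ensemble

        params = SurrogateParams(n_traj=120, seed=5, hop_latency=60.0, hop_tau=120.0)
        ens = generate_ensemble(params)
        s0 = population_trace(ens, S0)
        t = ens.time_grid
        cdf = 1.0 - np.exp(-np.clip(t - params.hop_latency, 0, None) / params.hop_tau)
        binom = 3.0 * np.sqrt(np.maximum(cdf * (1 - cdf), 1e-4) / params.n_traj)
        assert np.all(np.abs(s0 - cdf) <= binom + 0.05)


class TestExpectation:
    def test_constant_coordinate(self, small_ensemble):
        series = expectation(small_ensemble, lambda g: 2.5)
        np.testing.assert_allclose(np.asarray(series), 2.5, atol=1e-12)

    def test_weighted_mean_arithmetic_oracle(self, two_traj_ensemble):
        coord = pair_distance_coordinate("C3", "C4")
        series = expectation(two_traj_ensemble, coord)
        # hand-computed: t=10 -> 0.25*1.5 + 0.75*2.0
        assert series[1] == pytest.approx(0.25 * 1.5 + 0.75 * 2.0, abs=1e-9)

    def test_state_filter_and_masking(self, two_traj_ensemble):
        coord = pair_distance_coordinate("C3", "C4")
        s1_series = expectation(two_traj_ensemble, coord, state=S1)
        assert s1_series[1] == pytest.approx(2.0, abs=1e-9)  # only traj 2 in S1
        assert bool(s1_series.mask[2])  # no S1 population left -> masked

    def test_linearity_and_weight_rescaling(self, two_traj_ensemble):
        coord = pair_distance_coordinate("C3", "C4")
        base = np.asarray(expectation(two_traj_ensemble, coord))
        doubled = np.asarray(
            expectation(two_traj_ensemble, lambda g: 2.0 * coord(g))
        )
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-9)


class TestDensityProjection:
    def test_single_trajectory_gaussian_center(self, reactant):
        times = [0.0, 10.0]
        traj = _toy_trajectory(reactant, times, [1.5, 1.5], [S1, S1], 1.0)
        ens = WavepacketEnsemble([traj], np.asarray(times))
        cx = pair_distance_coordinate("C3", "C4")
        cy = pair_distance_coordinate("C3", "C10")
        grid = density_projection_2d(ens, cx, cy, t=0.0, kernel_widths=(0.05, 0.05))
        gx, gy = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        assert grid.x[gx] == pytest.approx(cx(traj.geometry_at(0)), abs=0.01)
        assert grid.y[gy] == pytest.approx(cy(traj.geometry_at(0)), abs=0.01)

    def test_integrates_to_s1_population(self, small_ensemble):
        cx = pair_distance_coordinate("C3", "C4")
        cy = pair_distance_coordinate("C3", "C10")
        t = 100.0
        grid = density_projection_2d(small_ensemble, cx, cy, t, kernel_widths=(0.05, 0.05))
        pop = population_trace(small_ensemble, S1)[small_ensemble.time_index(t)]
        assert grid.integral() == pytest.approx(pop, abs=1e-3)

    def test_marginal_consistency(self, small_ensemble):
        cx = pair_distance_coordinate("C3", "C4")
        cy = pair_distance_coordinate("C3", "C10")
        grid = density_projection_2d(small_ensemble, cx, cy, 100.0, kernel_widths=(0.04, 0.04))
        marg = grid.marginal_x()
        geoms, w = small_ensemble.geometries_at(100.0, S1)
        xs = np.array([cx(g) for g in geoms])
        direct = np.zeros_like(grid.x)
        for xi, wi in zip(xs, w):
            direct += wi * np.exp(-((grid.x - xi) ** 2) / (2 * 0.04**2)) / (
                0.04 * np.sqrt(2 * np.pi)
            )
        np.testing.assert_allclose(marg, direct, atol=1e-3)

    def test_anticorrelated_relaxation(self, small_ensemble):
        """During S1 relaxation the reporter distance falls as psi rises."""
        geoms, w = small_ensemble.geometries_at(100.0, S1)
        xs = np.array([pair_distance_coordinate("C3", "C10")(g) for g in geoms])
        ys = np.array([psi_sum_coordinate()(g) for g in geoms])
        assert np.corrcoef(xs, ys)[0, 1] < 0.0

    def test_empty_state_gives_zero_field(self, two_traj_ensemble):
        cx = pair_distance_coordinate("C3", "C4")
        grid = density_projection_2d(two_traj_ensemble, cx, cx, t=20.0)
        assert np.all(grid.density == 0.0)


class TestBranching:
    def test_all_open_toy(self, reactant):
        times = [0.0, 10.0]
        t1 = _toy_trajectory(reactant, times, [1.5, 3.0], [S1, S0], 1.0)
        ens = WavepacketEnsemble([t1], np.asarray(times))
        assert branching_fraction(ens) == 1.0

    def test_monotone_in_threshold(self, small_ensemble):
        fr = [
            branching_fraction(small_ensemble, open_threshold=thr)
            for thr in (1.8, 2.0, 2.5, 3.0)
        ]
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_no_s0_population_raises(self, reactant):
        times = [0.0, 10.0]
        t1 = _toy_trajectory(reactant, times, [1.5, 1.5], [S1, S1], 1.0)
        ens = WavepacketEnsemble([t1], np.asarray(times))
        with pytest.raises(ValueError):
            branching_fraction(ens)

    def test_binomial_recovery(self):
        from terpued.surrogate import SurrogateParams, generate_ensemble

        p = 0.30
        n = 400
        ens = generate_ensemble(SurrogateParams(n_traj=n, p_open=p, seed=21))
        est = branching_fraction(ens)
        assert abs(est - p) <= 3.0 * np.sqrt(p * (1 - p) / n)


class TestEnsembleInvariants:
    def test_weights_must_sum_to_one(self, reactant):
        times = [0.0, 10.0]
        t1 = _toy_trajectory(reactant, times, [1.5, 1.5], [S1, S1], 0.7)
        with pytest.raises(ValueError):
            WavepacketEnsemble([t1], np.asarray(times))

    def test_resampling_to_coarser_grid(self, reactant):
        times = np.arange(0.0, 100.0, 5.0)
        vals = np.linspace(1.5, 3.0, times.size)
        traj = _toy_trajectory(reactant, times, vals, [S1] * times.size, 1.0)
        coarse = traj.resampled(np.arange(0.0, 95.0, 25.0))
        i3, i4 = reactant.carbon_index("C3"), reactant.carbon_index("C4")
        d = np.linalg.norm(coarse.positions[:, i4] - coarse.positions[:, i3], axis=1)
        np.testing.assert_allclose(d, np.interp(coarse.times, times, vals), atol=1e-9)
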