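"""Builders, anchors, thermal sampling and the trajectory generator."""

import numpy as np
import pytest

from terpued.ensemble import S0, S1, branching_fraction, expectation, population_trace
from terpued.geometry import (
    BondTopology,
    cis_trans_label,
    coordination_sphere,
    pair_distance,
    pair_distance_coordinate,
)
from terpued.surrogate import (
    OPEN_ISOMERS,
    SurrogateParams,
    broadened_spectrum,
    build_open_product,
    build_terpinene,
    generate_ensemble,
    pericyclic_anchor,
    ring_open_ci_anchor,
    sample_thermal,
    select_initial_conditions,
)


class TestBuilders:
    def test_composition_and_labels(self, reactant):
        assert sum(1 for e in reactant.elements if e == "C") == 10
        assert sum(1 for e in reactant.elements if e == "H") == 16
        assert set(reactant.carbon_map) == {f"C{i}" for i in range(1, 11)}

    def test_topology_examples_on_built_geometry(self, reactant):
        topo = BondTopology.reactant()
        assert coordination_sphere(topo, "C3", "C5") == 2
        assert cis_trans_label(reactant, topo, "C3", "C10") == "trans"

    def test_reporter_distance(self, reactant):
        assert abs(pair_distance(reactant, "C3", "C10") - 3.9) <= 0.15

    def test_bond_lengths_physical(self, reactant):
        assert 1.30 <= pair_distance(reactant, "C1", "C6") <= 1.38  # double
        assert 1.45 <= pair_distance(reactant, "C3", "C4") <= 1.62  # sp3 sigma

    def test_rotamers_distinct_and_deterministic(self, reactant_rotamers):
        g1, g2, g3 = reactant_rotamers
        assert not np.allclose(g1.positions, g2.positions)
        assert not np.allclose(g2.positions, g3.positions)
        assert np.allclose(build_terpinene(2).positions, g2.positions)

    def test_invalid_rotamer_rejected(self):
        with pytest.raises(ValueError):
            build_terpinene(4)

    def test_anchor_critical_distances(self, reactant):
        peri = pericyclic_anchor(reactant)
        meci = ring_open_ci_anchor(reactant)
        assert pair_distance(peri, "C3", "C4") == pytest.approx(1.6, abs=0.01)
        assert pair_distance(meci, "C3", "C4") == pytest.approx(2.2, abs=0.01)
        assert abs(pair_distance(peri, "C3", "C10") - 3.55) < 0.1

    def test_open_products(self):
        for iso in OPEN_ISOMERS:
            g = build_open_product(iso)
            assert pair_distance(g, "C3", "C4") > 2.5
        with pytest.raises(ValueError):
            build_open_product("cEc")


class TestThermalSampling:
    def test_zero_sigma_copies(self, reactant):
        out = sample_thermal(reactant, 0.0, 3, seed=1)
        for g in out:
            np.testing.assert_array_equal(g.positions, reactant.positions)

    def test_sample_mean_clt(self, reactant):
        n = 200
        sigma = 0.03
        out = sample_thermal(reactant, sigma, n, seed=2)
        mean = np.mean([g.positions for g in out], axis=0)
        # hydrogens have 2 sigma displacements; bound everything by that
        assert np.all(np.abs(mean - reactant.positions) < 4 * 2 * sigma / np.sqrt(n))

    def test_seed_reproducibility(self, reactant):
        a = sample_thermal(reactant, 0.03, 4, seed=7)
        b = sample_thermal(reactant, 0.03, 4, seed=7)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.positions, gb.positions)


class TestGenerator:
    def test_p_open_zero_never_opens(self):
        ens = generate_ensemble(SurrogateParams(n_traj=20, p_open=0.0, seed=3))
        assert branching_fraction(ens) == 0.0

    def test_s1_sigma_bond_intact_s0_opens(self, small_ensemble):
        coord = pair_distance_coordinate("C3", "C4")
        s1 = expectation(small_ensemble, coord, state=S1)
        s0 = expectation(small_ensemble, coord, state=S0)
        s1_vals = np.asarray(s1)[~s1.mask]
        assert np.all(s1_vals < 1.9)
        assert np.asarray(s0)[-1] > 2.2

    def test_s1_geometries_keep_sigma_bond_per_frame(self, small_ensemble):
        coord = pair_distance_coordinate("C3", "C4")
        for traj in small_ensemble.trajectories:
            for k in range(traj.n_frames):
                if traj.states[k] == S1:
                    r = coord(traj.geometry_at(k))
                    assert 1.40 <= r <= 1.95

    def test_bit_reproducible(self):
        p = SurrogateParams(n_traj=5, seed=99)
        a = generate_ensemble(p)
        b = generate_ensemble(p)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.positions, tb.positions)
            np.testing.assert_array_equal(ta.states, tb.states)

    def test_population_conservation(self, small_ensemble):
        total = population_trace(small_ensemble, S0) + population_trace(small_ensemble, S1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_reporter_dip_near_configured_time(self, small_ensemble):
        from terpued.pipeline import dip_time

        assert abs(dip_time(small_ensemble) - 100.0) <= 50.0

    def test_branching_recovery_at_study_conditions(self):
        ens = generate_ensemble(SurrogateParams(n_traj=400, seed=8))
        est = branching_fraction(ens)
        assert abs(est - 0.58) <= 3 * np.sqrt(0.58 * 0.42 / 400)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SurrogateParams(p_open=1.2)
        with pytest.raises(ValueError):
            SurrogateParams(hop_tau=-1.0)


class TestSpectrumTools:
    def test_single_line_peak_and_fwhm(self):
        grid, spec = broadened_spectrum([5.0], [2.0], fwhm=0.2)
        assert grid[np.argmax(spec)] == pytest.approx(5.0, abs=0.005)
        half = spec.max() / 2
        above = grid[spec >= half]
        assert above[-1] - above[0] == pytest.approx(0.2, abs=0.01)

    def test_two_equal_lines(self):
        grid, spec = broadened_spectrum([4.0, 6.0], [1.0, 1.0], fwhm=0.2)
        peaks = [grid[np.argmin(np.abs(grid - e))] for e in (4.0, 6.0)]
        v = [spec[np.argmin(np.abs(grid - p))] for p in peaks]
        assert v[0] == pytest.approx(v[1], rel=1e-6)

    def test_integral_equals_total_strength(self):
        grid, spec = broadened_spectrum([4.5, 5.1, 5.3], [1.0, 0.4, 2.2], fwhm=0.2)
        assert np.trapezoid(spec, grid) == pytest.approx(3.6, abs=1e-6)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            broadened_spectrum([1.0], [1.0, 2.0])

    def test_selection_window_arithmetic(self):
        # 5.05 - 0.4 = 4.65 -> selected; 5.36 - 0.4 = 4.96, |delta| = 0.31 -> rejected
        assert select_initial_conditions([5.05]) == [0]
        assert select_initial_conditions([5.36]) == []
        assert select_initial_conditions([]) == []
        assert select_initial_conditions([5.05, 5.36, 4.80]) == [0, 2]


class TestLabelInference:
    def test_recovers_builder_labels(self, reactant):
        from terpued.geometry import MolecularGeometry
        from terpued.surrogate import infer_carbon_labels

        # strip labels and shuffle atom order
        rng = np.random.default_rng(0)
        perm = rng.permutation(reactant.n_atoms)
        shuffled = MolecularGeometry(
            tuple(reactant.elements[i] for i in perm), reactant.positions[perm]
        )
        labels = infer_carbon_labels(shuffled)
        for lbl, idx in labels.items():
            assert int(perm[idx]) == reactant.carbon_map[lbl]

    def test_rejects_open_chain(self):
        from terpued.geometry import GeometryError
        from terpued.surrogate import build_open_product, infer_carbon_labels

        g = build_open_product("cZt")
        unlabelled = type(g)(g.elements, g.positions)
        with pytest.raises(GeometryError):
            infer_carbon_labels(unlabelled)
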