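"""Geometry primitives: distances, spheres, cis/trans, conrotatory angles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from terpued.geometry import (
    CARBON_LABELS,
    AssignmentError,
    BondTopology,
    GeometryError,
    LabelError,
    MolecularGeometry,
    TopologyError,
    cis_trans_label,
    conrotatory_phi,
    conrotatory_psi,
    coordination_sphere,
    dihedral_angle,
    pair_distance,
)

from conftest import random_rigid_motion

TOPOLOGY = BondTopology.reactant()


class TestPairDistance:
    def test_identity_is_zero(self, reactant):
        assert pair_distance(reactant, "C3", "C3") == 0.0

    def test_symmetric(self, reactant):
        assert pair_distance(reactant, "C3", "C10") == pair_distance(
            reactant, "C10", "C3"
        )

    def test_matches_componentwise_formula(self, rng):
        # brute-force oracle: sqrt(sum of squared coordinate differences)
        pos = rng.normal(scale=3.0, size=(2, 3))
        geom = MolecularGeometry(("C", "C"), pos, {"C1": 0, "C2": 1})
        expected = np.sqrt(((pos[0] - pos[1]) ** 2).sum())
        assert pair_distance(geom, "C1", "C2") == pytest.approx(expected, abs=1e-12)

    def test_unknown_label_raises(self, reactant):
        with pytest.raises(LabelError):
            pair_distance(reactant, "C3", "C99")


class TestCoordinationSphere:
    def test_paper_examples(self):
        assert coordination_sphere(TOPOLOGY, "C3", "C5") == 2
        assert coordination_sphere(TOPOLOGY, "C3", "C10") == 3

    def test_bonded_pairs_are_sphere_one(self):
        for bond in TOPOLOGY.bonds:
            a, b = tuple(bond)
            assert coordination_sphere(TOPOLOGY, a, b) == 1

    def test_matches_bfs_oracle_on_all_pairs(self):
        # independent breadth-first-search oracle over the bond graph
        adj = {l: set() for l in CARBON_LABELS}
        for bond in TOPOLOGY.bonds:
            a, b = tuple(bond)
            adj[a].add(b)
            adj[b].add(a)

        def bfs(src, dst):
            frontier, seen, depth = {src}, {src}, 0
            while dst not in frontier:
                frontier = {n for f in frontier for n in adj[f]} - seen
                seen |= frontier
                depth += 1
            return depth

        for a, b in combinations(CARBON_LABELS, 2):
            assert coordination_sphere(TOPOLOGY, a, b) == bfs(a, b)

    def test_triangle_inequality(self):
        for a, b, c in combinations(CARBON_LABELS, 3):
            assert coordination_sphere(TOPOLOGY, a, c) <= coordination_sphere(
                TOPOLOGY, a, b
            ) + coordination_sphere(TOPOLOGY, b, c)

    def test_sphere_one_count_and_degrees(self):
        graph = TOPOLOGY.graph()
        assert graph.number_of_edges() == 10
        assert graph.degree("C2") == 3
        assert graph.degree("C10") == 1

    def test_disconnected_raises(self):
        topo = BondTopology(frozenset({frozenset(("C1", "C3")), frozenset(("C5", "C10"))}))
        with pytest.raises(TopologyError):
            coordination_sphere(topo, "C1", "C10")


class TestCisTrans:
    def test_paper_examples_on_reactant(self, reactant):
        assert cis_trans_label(reactant, TOPOLOGY, "C3", "C9") == "cis"
        assert cis_trans_label(reactant, TOPOLOGY, "C3", "C10") == "trans"

    def test_planar_chain_zero_dihedral_is_cis(self):
        geom = MolecularGeometry(
            ("C",) * 4,
            [[0, 1, 0], [0, 0, 0], [1.5, 0, 0], [1.5, 1, 0]],
            {"C3": 0, "C1": 1, "C6": 2, "C9": 3},
        )
        topo = BondTopology(
            frozenset(
                frozenset(b) for b in [("C3", "C1"), ("C1", "C6"), ("C6", "C9")]
            )
        )
        assert cis_trans_label(geom, topo, "C3", "C9") == "cis"

    def test_non_third_sphere_raises(self, reactant):
        with pytest.raises(TopologyError):
            cis_trans_label(reactant, TOPOLOGY, "C3", "C5")

    def test_every_third_sphere_pair_labelled(self, reactant):
        n = 0
        for a, b in combinations(CARBON_LABELS, 2):
            if coordination_sphere(TOPOLOGY, a, b) == 3:
                assert cis_trans_label(reactant, TOPOLOGY, a, b) in ("cis", "trans")
                n += 1
        assert n > 0

    def test_mirror_invariant(self, reactant):
        mirrored = reactant.with_positions(reactant.positions * [-1.0, 1.0, 1.0])
        for a, b in combinations(CARBON_LABELS, 2):
            if coordination_sphere(TOPOLOGY, a, b) == 3:
                assert cis_trans_label(reactant, TOPOLOGY, a, b) == cis_trans_label(
                    mirrored, TOPOLOGY, a, b
                )


class TestConrotatoryAngles:
    def test_rigid_motion_invariance(self, reactant, rng):
        phi0 = conrotatory_phi(reactant)
        psi0 = conrotatory_psi(reactant)
        for _ in range(100):
            rot, t = random_rigid_motion(rng)
            moved = reactant.transformed(rot, t)
            assert conrotatory_phi(moved).phi_sum == pytest.approx(
                phi0.phi_sum, abs=1e-6
            )
            assert conrotatory_psi(moved).psi_sum == pytest.approx(
                psi0.psi_sum, abs=1e-6
            )

    def test_pair_distance_rigid_invariance(self, reactant, rng):
        d0 = pair_distance(reactant, "C3", "C10")
        rot, t = random_rigid_motion(rng)
        assert pair_distance(reactant.transformed(rot, t), "C3", "C10") == pytest.approx(
            d0, abs=1e-6
        )

    def test_phi_coincident_planes_sum_to_zero(self):
        # CH2 planes constructed to coincide with their reference planes
        geom = _phi_toy(0.0, 0.0)
        angles = conrotatory_phi(geom)
        assert angles.phi_sum == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 25.0, -40.0])
    def test_phi_recovers_constructed_rotation(self, theta):
        # rotate only the C3-side CH2 about an in-plane axis by a known angle
        angles = conrotatory_phi(_phi_toy(theta, 0.0))
        assert abs(angles.phi_c3) == pytest.approx(abs(theta), abs=1e-6)
        flipped = conrotatory_phi(_phi_toy(-theta, 0.0))
        assert flipped.phi_c3 == pytest.approx(-angles.phi_c3, abs=1e-6)

    def test_phi_sides_independent(self):
        one = conrotatory_phi(_phi_toy(20.0, 0.0))
        assert one.phi_c4 == pytest.approx(0.0, abs=1e-9)
        assert one.phi_sum == pytest.approx(one.phi_c3, abs=1e-9)

    def test_psi_planar_arrangement_is_zero(self):
        geom = _psi_toy(0.0)
        assert conrotatory_psi(geom).psi_sum == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [12.0, 30.0])
    def test_psi_recovers_out_of_plane_rotation(self, theta):
        # C10 rotated out of the skeleton plane about the C4-C5 axis, which
        # lies in both the reference and the moving plane, so the recovered
        # plane-plane angle equals the constructed rotation exactly
        geom = _psi_toy(theta)
        psi = conrotatory_psi(geom)
        assert abs(psi.psi_c5side) == pytest.approx(theta, abs=1e-6)
        assert psi.psi_c1side == pytest.approx(0.0, abs=1e-9)

    def test_psi_collinear_reference_raises(self):
        pts = {l: [i * 1.0, 0.0, 0.0] for i, l in enumerate(CARBON_LABELS)}
        geom = MolecularGeometry(
            ("C",) * 10,
            [pts[l] for l in CARBON_LABELS],
            {l: i for i, l in enumerate(CARBON_LABELS)},
        )
        with pytest.raises(GeometryError):
            conrotatory_psi(geom)

    def test_phi_missing_hydrogens_raises(self, reactant):
        stripped = MolecularGeometry(
            tuple(e for e in reactant.elements if e == "C"),
            reactant.positions[:10],
            dict(reactant.carbon_map),
        )
        with pytest.raises(AssignmentError):
            conrotatory_phi(stripped)


def test_dihedral_sign_antisymmetry():
    p = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.5, 0.8]])
    d1 = dihedral_angle(*p)
    mirrored = p * [1.0, 1.0, -1.0]
    assert dihedral_angle(*mirrored) == pytest.approx(-d1, abs=1e-12)


def _phi_toy(theta_c3: float, theta_c4: float) -> MolecularGeometry:
    """C10H16-labelled toy in which each CH2 plane starts in its reference plane.

    The C3-C4 direction lies inside both reference planes, so rotating a CH2
    pair about it by theta produces a plane-plane angle of exactly theta.
    """
    pos = {
        "C3": np.array([0.0, 0.0, 0.0]),
        "C4": np.array([1.6, 0.0, 0.0]),
        "C1": np.array([-0.8, 1.2, 0.0]),
        "C2": np.array([-2.3, 1.4, 0.0]),
        "C5": np.array([2.4, 1.2, 0.0]),
        "C10": np.array([3.9, 1.4, 0.0]),
        "C6": np.array([-0.2, 2.5, 0.3]),
        "C9": np.array([1.2, 2.9, 0.3]),
        "C7": np.array([-3.0, 2.7, 0.1]),
        "C8": np.array([-3.1, 0.2, -0.1]),
    }

    def rot_x(p, theta, center):
        th = np.radians(theta)
        rel = p - center
        rotm = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        return center + rotm @ rel

    # CH2 hydrogens initially inside the respective reference planes
    h3a = pos["C3"] + np.array([-0.4, -0.95, 0.0])
    h3b = pos["C3"] + np.array([0.75, -0.75, 0.0])
    h4a = pos["C4"] + np.array([0.4, -0.95, 0.0])
    h4b = pos["C4"] + np.array([-0.75, -0.75, 0.0])
    h3a = rot_x(h3a, theta_c3, pos["C3"])
    h3b = rot_x(h3b, theta_c3, pos["C3"])
    h4a = rot_x(h4a, theta_c4, pos["C4"])
    h4b = rot_x(h4b, theta_c4, pos["C4"])
    labels = list(CARBON_LABELS)
    coords = [pos[l] for l in labels] + [h3a, h3b, h4a, h4b]
    elements = ("C",) * 10 + ("H",) * 4
    return MolecularGeometry(elements, np.array(coords), {l: i for i, l in enumerate(labels)})


def _psi_toy(theta_c10: float) -> MolecularGeometry:
    """Planar hexagonal skeleton; C10 rotated out of plane about C4-C5."""
    pos = {
        "C1": np.array([0.0, 0.0, 0.0]),
        "C6": np.array([1.4, 0.0, 0.0]),
        "C9": np.array([2.1, 1.21, 0.0]),
        "C5": np.array([1.4, 2.42, 0.0]),
        "C4": np.array([0.0, 2.42, 0.0]),
        "C3": np.array([-0.7, 1.21, 0.0]),
        "C2": np.array([-0.7, -1.21, 0.0]),
        "C10": np.array([2.1, 3.63, 0.0]),
        "C7": np.array([-2.2, -1.21, 0.0]),
        "C8": np.array([0.0, -2.42, 0.0]),
    }
    axis = pos["C5"] - pos["C4"]
    k = axis / np.linalg.norm(axis)
    th = np.radians(theta_c10)
    rel = pos["C10"] - pos["C5"]
    pos["C10"] = pos["C5"] + (
        rel * np.cos(th)
        + np.cross(k, rel) * np.sin(th)
        + k * np.dot(k, rel) * (1 - np.cos(th))
    )
    labels = list(CARBON_LABELS)
    return MolecularGeometry(
        ("C",) * 10,
        np.array([pos[l] for l in labels]),
        {l: i for i, l in enumerate(labels)},
    )
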