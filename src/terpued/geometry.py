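"""Molecular geometry, fixed bond topology and ring-opening reaction coordinates.

The package analyses the photochemical electrocyclic ring-opening of
alpha-terpinene (1-methyl-4-isopropyl-1,3-cyclohexadiene).  All structural
bookkeeping uses a fixed carbon numbering C1..C10:

* ring: C1-C3, C1-C6, C6-C9, C9-C5, C5-C4, C4-C3 (the sigma bond that breaks
  is C3-C4; the reactant double bonds are C1=C6 and C9=C5),
* substituents: the isopropyl group C2(H)(C7H3)(C8H3) on C1 and the methyl
  C10H3 on C5.

The bond topology is the *reactant* topology and is deliberately never
re-derived from interatomic distances during dynamics, so that quantities such
as "the C3-C4 distance" or "third coordination sphere" remain meaningful after
the ring has opened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "CARBON_LABELS",
    "RING_BONDS",
    "SUBSTITUENT_BONDS",
    "GeometryError",
    "LabelError",
    "TopologyError",
    "AssignmentError",
    "MolecularGeometry",
    "BondTopology",
    "ConrotatoryAngles",
    "pair_distance",
    "coordination_sphere",
    "cis_trans_label",
    "conrotatory_phi",
    "conrotatory_psi",
    "dihedral_angle",
    "plane_normal",
    "best_fit_plane_normal",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent molecular geometry."""


class LabelError(KeyError):
    """Unknown carbon label."""


class TopologyError(ValueError):
    """Invalid request against the bond topology."""


class AssignmentError(GeometryError):
    """Hydrogen-to-carbon assignment is ambiguous or impossible."""


CARBON_LABELS: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 11))

RING_BONDS: tuple[tuple[str, str], ...] = (
    ("C1", "C3"),
    ("C1", "C6"),
    ("C6", "C9"),
    ("C9", "C5"),
    ("C5", "C4"),
    ("C4", "C3"),
)

SUBSTITUENT_BONDS: tuple[tuple[str, str], ...] = (
    ("C1", "C2"),
    ("C2", "C7"),
    ("C2", "C8"),
    ("C5", "C10"),
)

#: Formal bond orders of the closed reactant (used for template matching).
REACTANT_BOND_ORDERS: Mapping[frozenset, int] = {
    frozenset(b): 1 for b in RING_BONDS + SUBSTITUENT_BONDS
}
REACTANT_BOND_ORDERS = dict(REACTANT_BOND_ORDERS)
REACTANT_BOND_ORDERS[frozenset(("C1", "C6"))] = 2
REACTANT_BOND_ORDERS[frozenset(("C9", "C5"))] = 2

#: Formal bond orders of the open-chain triene photoproduct.
OPEN_BOND_ORDERS: Mapping[frozenset, int] = {
    frozenset(b): 1
    for b in RING_BONDS + SUBSTITUENT_BONDS
    if frozenset(b) != frozenset(("C4", "C3"))
}
OPEN_BOND_ORDERS = dict(OPEN_BOND_ORDERS)
OPEN_BOND_ORDERS[frozenset(("C1", "C3"))] = 2
OPEN_BOND_ORDERS[frozenset(("C6", "C9"))] = 2
OPEN_BOND_ORDERS[frozenset(("C5", "C4"))] = 2


@dataclass(frozen=True)
class MolecularGeometry:
    """Labelled atomic coordinates (Å).

    ``carbon_map`` maps carbon labels (e.g. ``"C3"``) to row indices of
    ``positions``.  Toy molecules used in diffraction tests may carry an empty
    map; the alpha-terpinene constructors always provide the full C1..C10 map.
    """

    elements: tuple[str, ...]
    positions: np.ndarray
    carbon_map: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError(f"positions must be (n, 3), got {pos.shape}")
        if pos.shape[0] != len(self.elements):
            raise GeometryError(
                f"{len(self.elements)} elements but {pos.shape[0]} positions"
            )
        if not np.all(np.isfinite(pos)):
            raise GeometryError("non-finite coordinates")
        object.__setattr__(self, "positions", pos)
        seen: dict[int, str] = {}
        for label, idx in self.carbon_map.items():
            if not 0 <= idx < pos.shape[0]:
                raise LabelError(f"label {label} maps to out-of-range index {idx}")
            if self.elements[idx] != "C":
                raise LabelError(f"label {label} maps to a {self.elements[idx]} atom")
            if idx in seen:
                raise LabelError(f"labels {seen[idx]} and {label} map to atom {idx}")
            seen[idx] = label

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def carbon_index(self, label: str) -> int:
        try:
            return self.carbon_map[label]
        except KeyError:
            raise LabelError(f"unknown carbon label {label!r}") from None

    def carbon_position(self, label: str) -> np.ndarray:
        return self.positions[self.carbon_index(label)]

    def with_positions(self, positions: np.ndarray) -> "MolecularGeometry":
        return MolecularGeometry(self.elements, positions, self.carbon_map)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularGeometry":
        """Apply a rigid motion ``x -> R x + t``."""
        rotation = np.asarray(rotation, float)
        return self.with_positions(self.positions @ rotation.T + np.asarray(translation, float))

    def hydrogens_near(self, label: str, cutoff: float = 1.3) -> list[int]:
        """Indices of hydrogens within ``cutoff`` Å of the labelled carbon."""
        c = self.carbon_position(label)
        idx = [
            i
            for i, el in enumerate(self.elements)
            if el == "H" and np.linalg.norm(self.positions[i] - c) <= cutoff
        ]
        idx.sort(key=lambda i: float(np.linalg.norm(self.positions[i] - c)))
        return idx


def _terpinene_checks(geom: MolecularGeometry) -> None:
    n_c = sum(1 for e in geom.elements if e == "C")
    n_h = sum(1 for e in geom.elements if e == "H")
    if n_c != 10 or n_h != 16:
        raise GeometryError(
            f"alpha-terpinene requires C10H16, got C{n_c}H{n_h}"
        )
    if set(geom.carbon_map) != set(CARBON_LABELS):
        raise LabelError("carbon_map must cover C1..C10 exactly")


@dataclass(frozen=True)
class BondTopology:
    """Unordered carbon-carbon bond set with a path-length (sphere) metric."""

    bonds: frozenset

    def __post_init__(self) -> None:
        for b in self.bonds:
            if len(b) != 2:
                raise TopologyError(f"bond {set(b)} is not a pair")

    @classmethod
    def reactant(cls) -> "BondTopology":
        """The fixed closed-ring reactant topology of alpha-terpinene."""
        return cls(frozenset(frozenset(b) for b in RING_BONDS + SUBSTITUENT_BONDS))

    @classmethod
    def open_product(cls) -> "BondTopology":
        """Reactant topology minus the broken C3-C4 sigma bond."""
        bonds = {frozenset(b) for b in RING_BONDS + SUBSTITUENT_BONDS}
        bonds.discard(frozenset(("C3", "C4")))
        return cls(frozenset(bonds))

    def graph(self) -> nx.Graph:
        return _topology_graph(self.bonds)

    @property
    def labels(self) -> frozenset:
        return frozenset(l for b in self.bonds for l in b)


@lru_cache(maxsize=8)
def _topology_graph(bonds: frozenset) -> nx.Graph:
    g = nx.Graph()
    # sorted insertion keeps traversal order independent of hash randomization
    for a, c in sorted(tuple(sorted(b)) for b in bonds):
        g.add_edge(a, c)
    return g


def pair_distance(geom: MolecularGeometry, a: str, b: str) -> float:
    """Euclidean distance (Å) between two labelled carbons."""
    return float(np.linalg.norm(geom.carbon_position(a) - geom.carbon_position(b)))


def coordination_sphere(topology: BondTopology, a: str, b: str) -> int:
    """Shortest bond-path length between two carbons in the fixed topology.

    Sphere 1 pairs are bonded, sphere 2 pairs are geminal, sphere 3 pairs are
    separated by a central bond and carry a cis/trans conformation label.
    """
    g = topology.graph()
    for lbl in (a, b):
        if lbl not in g:
            raise TopologyError(f"label {lbl!r} not in topology")
    try:
        return int(nx.shortest_path_length(g, a, b))
    except nx.NetworkXNoPath:
        raise TopologyError(f"{a} and {b} are disconnected") from None


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise GeometryError("collinear atoms in dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / norm_b1))
    return float(np.degrees(np.arctan2(y, x)))


def cis_trans_label(
    geom: MolecularGeometry, topology: BondTopology, a: str, b: str
) -> str:
    """cis/trans conformation of a third-sphere carbon pair about its central bond.

    The dihedral a-x-y-b is evaluated along a shortest bond path a-x-y-b; the
    pair is *cis* when its magnitude is below 90 degrees, *trans* otherwise.
    """
    sphere = coordination_sphere(topology, a, b)
    if sphere != 3:
        raise TopologyError(
            f"cis/trans defined only for third-sphere pairs, ({a},{b}) is sphere {sphere}"
        )
    path = nx.shortest_path(topology.graph(), a, b)
    pts = [geom.carbon_position(l) for l in path]
    d = dihedral_angle(*pts)
    return "cis" if abs(d) < 90.0 else "trans"


# --------------------------------------------------------------------------
# Conrotatory planarization (phi) / deplanarization (psi) coordinates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConrotatoryAngles:
    """Signed plane-plane angles (degrees) tracking CH2 rehybridization.

    phi compares each terminal CH2 plane with the plane of the product double
    bond forming at that carbon; psi compares the substituent planes with the
    best-fit plane of the conjugated diene carbons.  Sums are conrotatory:
    signs are chosen so that conrotatory motion adds and disrotatory motion
    cancels.
    """

    phi_c3: float | None = None
    phi_c4: float | None = None
    phi_sum: float | None = None
    psi_c1side: float | None = None
    psi_c5side: float | None = None
    psi_sum: float | None = None


def plane_normal(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Unit normal of the plane through three points."""
    n = np.cross(np.asarray(p1, float) - p0, np.asarray(p2, float) - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("collinear plane-defining atoms")
    return n / norm


def best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane (smallest principal component)."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise GeometryError("plane-defining atoms are collinear")
    return vt[-1]


def _ring_circulation_normal(geom: MolecularGeometry) -> np.ndarray:
    """Orientation reference: right-hand normal of the C1->C6->C9->C5 circuit."""
    pts = np.array([geom.carbon_position(l) for l in ("C1", "C6", "C9", "C5")])
    center = pts.mean(axis=0)
    n = np.zeros(3)
    for i in range(4):
        n += np.cross(pts[i] - center, pts[(i + 1) % 4] - center)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate diene ring")
    return n / norm


def _signed_plane_angle(
    n_ref: np.ndarray, n_mov: np.ndarray, axis: np.ndarray
) -> float:
    """Signed angle between two planes, in [-90, 90] degrees.

    The moving normal is flipped into the hemisphere of the reference normal
    (plane normals are only defined up to sign); the sign of the angle is the
    sign of the scalar triple product n_ref . (n_mov x axis).
    """
    if float(np.dot(n_ref, n_mov)) < 0.0:
        n_mov = -n_mov
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    cosang = float(np.clip(np.dot(n_ref, n_mov), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    sign = float(np.dot(n_ref, np.cross(n_mov, axis)))
    return ang if sign >= 0.0 else -ang


def _ch2_hydrogens(geom: MolecularGeometry, label: str, cutoff: float = 1.3) -> tuple[int, int]:
    """The two CH2 hydrogens of C3 or C4, by nearest-distance assignment."""
    cand = geom.hydrogens_near(label, cutoff)
    if len(cand) < 2:
        raise AssignmentError(
            f"{label} has {len(cand)} hydrogens within {cutoff} Å, need 2"
        )
    carbons = [i for i, e in enumerate(geom.elements) if e == "C"]
    cpos = geom.positions[carbons]
    own = geom.carbon_index(label)
    chosen = cand[:2]
    for h in chosen:
        d = np.linalg.norm(cpos - geom.positions[h], axis=1)
        order = np.argsort(d)
        nearest = carbons[int(order[0])]
        if nearest != own and d[order[0]] < d[list(carbons).index(own)] - 1e-3:
            raise AssignmentError(
                f"hydrogen {h} is nearer to atom {nearest} than to {label}"
            )
        if len(order) > 1 and abs(d[order[0]] - d[order[1]]) < 1e-3:
            raise AssignmentError(f"hydrogen {h} is equidistant to two carbons")
    return chosen[0], chosen[1]


def conrotatory_phi(geom: MolecularGeometry) -> ConrotatoryAngles:
    """Conrotatory planarization coordinate phi.

    phi_c3 is the signed angle between the C3 CH2 plane and the C1,C2,C3
    plane; phi_c4 between the C4 CH2 plane and the C4,C5,C10 plane.  Signs use
    side axes C3->C1 and C4->C5 and reference normals oriented by the ring
    circulation, so that a conrotatory twist of the two CH2 groups gives
    contributions of equal sign.
    """
    n_circ = _ring_circulation_normal(geom)

    def side(carbon: str, ref_labels: tuple[str, str, str], axis_to: str) -> float:
        h1, h2 = _ch2_hydrogens(geom, carbon)
        n_mov = plane_normal(
            geom.carbon_position(carbon), geom.positions[h1], geom.positions[h2]
        )
        n_ref = plane_normal(*(geom.carbon_position(l) for l in ref_labels))
        if float(np.dot(n_ref, n_circ)) < 0.0:
            n_ref = -n_ref
        axis = geom.carbon_position(axis_to) - geom.carbon_position(carbon)
        return _signed_plane_angle(n_ref, n_mov, axis)

    phi_c3 = side("C3", ("C1", "C2", "C3"), "C1")
    phi_c4 = side("C4", ("C4", "C5", "C10"), "C5")
    return ConrotatoryAngles(phi_c3=phi_c3, phi_c4=phi_c4, phi_sum=phi_c3 + phi_c4)


def conrotatory_psi(geom: MolecularGeometry) -> ConrotatoryAngles:
    """Conrotatory deplanarization coordinate psi.

    The reference plane is the least-squares plane through the conjugated
    diene carbons C1, C6, C9, C5; the moving planes are (C1,C2,C3) and
    (C4,C5,C10).  Side axes are C3->C1 and C4->C5.
    """
    ref_pts = np.array([geom.carbon_position(l) for l in ("C1", "C6", "C9", "C5")])
    n_ref = best_fit_plane_normal(ref_pts)
    n_circ = _ring_circulation_normal(geom)
    if float(np.dot(n_ref, n_circ)) < 0.0:
        n_ref = -n_ref

    n1 = plane_normal(*(geom.carbon_position(l) for l in ("C1", "C2", "C3")))
    axis1 = geom.carbon_position("C1") - geom.carbon_position("C3")
    psi_c1 = _signed_plane_angle(n_ref, n1, axis1)

    n2 = plane_normal(*(geom.carbon_position(l) for l in ("C4", "C5", "C10")))
    axis2 = geom.carbon_position("C5") - geom.carbon_position("C4")
    psi_c5 = _signed_plane_angle(n_ref, n2, axis2)

    return ConrotatoryAngles(
        psi_c1side=psi_c1, psi_c5side=psi_c5, psi_sum=psi_c1 + psi_c5
    )


def pair_distance_coordinate(a: str, b: str) -> Callable[[MolecularGeometry], float]:
    """Coordinate function ``geom -> pair_distance(geom, a, b)``."""

    def coord(geom: MolecularGeometry) -> float:
        return pair_distance(geom, a, b)

    coord.__name__ = f"r_{a}_{b}"
    return coord


def psi_sum_coordinate() -> Callable[[MolecularGeometry], float]:
    """Coordinate function returning the conrotatory deplanarization sum."""

    def coord(geom: MolecularGeometry) -> float:
        return float(conrotatory_psi(geom).psi_sum)

    coord.__name__ = "psi_sum"
    return coord


def phi_sum_coordinate() -> Callable[[MolecularGeometry], float]:
    """Coordinate function returning the conrotatory planarization sum."""

    def coord(geom: MolecularGeometry) -> float:
        return float(conrotatory_phi(geom).phi_sum)

    coord.__name__ = "phi_sum"
    return coord


def validate_terpinene(geom: MolecularGeometry) -> MolecularGeometry:
    """Check the C10H16 composition and full C1..C10 labelling."""
    _terpinene_checks(geom)
    return geom
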