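"""Internal-coordinate (Z-matrix) representation of alpha-terpinene.

Geometry morphing for the surrogate trajectory generator is done in internal
coordinates — bond lengths, bond angles and dihedrals interpolated, Cartesians
rebuilt — rather than by Cartesian linear interpolation, which collapses CH2
groups along curved paths.

The package uses a single canonical atom order for C10H16:

    index 0..9   : carbons C1..C10,
    index 10..25 : hydrogens, grouped by parent carbon
                   (C2:1, C3:2, C4:2, C6:1, C9:1, C7:3, C8:3, C10:3).

The Z-matrix construction tree contains the C3-C4 bond explicitly (so the
distance of the breaking sigma bond is a directly editable coordinate); the
ring is closed at the emergent C4-C5 bond, which is reproduced exactly at any
geometry converted to internals and back.

Rebuilding uses the natural-extension reference frame (NeRF) placement,
vectorised over a batch of frames.
"""

from __future__ import annotations

import numpy as np

from .geometry import CARBON_LABELS, GeometryError, MolecularGeometry

__all__ = [
    "CANONICAL_ELEMENTS",
    "HYDROGEN_PARENTS",
    "ZMATRIX",
    "to_internal",
    "to_internal_batch",
    "rebuild",
    "rebuild_batch",
    "interpolate",
    "canonical_carbon_map",
]

# canonical hydrogen slots: parent carbon label per hydrogen index 10..25
HYDROGEN_PARENTS: tuple[str, ...] = (
    "C2",
    "C3",
    "C3",
    "C4",
    "C4",
    "C6",
    "C9",
    "C7",
    "C7",
    "C7",
    "C8",
    "C8",
    "C8",
    "C10",
    "C10",
    "C10",
)

CANONICAL_ELEMENTS: tuple[str, ...] = ("C",) * 10 + ("H",) * 16

_C = {label: i for i, label in enumerate(CARBON_LABELS)}

# (atom, bond_ref, angle_ref, dihedral_ref) in construction order; refs are
# canonical indices of previously placed atoms.  None marks absent refs for
# the first three atoms.
ZMATRIX: tuple[tuple[int, int | None, int | None, int | None], ...] = (
    (_C["C5"], None, None, None),
    (_C["C9"], _C["C5"], None, None),
    (_C["C6"], _C["C9"], _C["C5"], None),
    (_C["C1"], _C["C6"], _C["C9"], _C["C5"]),
    (_C["C3"], _C["C1"], _C["C6"], _C["C9"]),
    (_C["C4"], _C["C3"], _C["C1"], _C["C6"]),
    (_C["C2"], _C["C1"], _C["C6"], _C["C9"]),
    (_C["C10"], _C["C5"], _C["C9"], _C["C6"]),
    (_C["C7"], _C["C2"], _C["C1"], _C["C6"]),
    (_C["C8"], _C["C2"], _C["C1"], _C["C7"]),
    (10, _C["C2"], _C["C1"], _C["C7"]),
    (11, _C["C3"], _C["C1"], _C["C6"]),
    (12, _C["C3"], _C["C1"], _C["C6"]),
    (13, _C["C4"], _C["C3"], _C["C1"]),
    (14, _C["C4"], _C["C3"], _C["C1"]),
    (15, _C["C6"], _C["C1"], _C["C3"]),
    (16, _C["C9"], _C["C5"], _C["C10"]),
    (17, _C["C7"], _C["C2"], _C["C1"]),
    (18, _C["C7"], _C["C2"], _C["C1"]),
    (19, _C["C7"], _C["C2"], _C["C1"]),
    (20, _C["C8"], _C["C2"], _C["C1"]),
    (21, _C["C8"], _C["C2"], _C["C1"]),
    (22, _C["C8"], _C["C2"], _C["C1"]),
    (23, _C["C10"], _C["C5"], _C["C9"]),
    (24, _C["C10"], _C["C5"], _C["C9"]),
    (25, _C["C10"], _C["C5"], _C["C9"]),
)

N_ATOMS = len(ZMATRIX)

#: Z-matrix rows whose dihedral column exists (entries 3..25).
_DIHEDRAL_ROWS = tuple(k for k, e in enumerate(ZMATRIX) if e[3] is not None)


def canonical_carbon_map() -> dict[str, int]:
    return dict(_C)


def _angles_batch(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c in radians, batched over leading axes."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals_batch(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in radians, batched."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b1u)
    return np.arctan2(y, x)


def to_internal_batch(positions: np.ndarray) -> np.ndarray:
    """Convert canonical-order Cartesians (T, 26, 3) to internals (T, 26, 3).

    Column 0 holds bond lengths (Å), column 1 bond angles (rad), column 2
    dihedrals (rad); unused slots of the first three rows are zero.
    """
    pos = np.asarray(positions, float)
    squeeze = pos.ndim == 2
    if squeeze:
        pos = pos[None]
    if pos.shape[-2] != N_ATOMS:
        raise GeometryError(f"expected {N_ATOMS} canonical atoms, got {pos.shape[-2]}")
    out = np.zeros((pos.shape[0], N_ATOMS, 3))
    for k, (atom, bref, aref, dref) in enumerate(ZMATRIX):
        if bref is None:
            continue
        out[:, k, 0] = np.linalg.norm(pos[:, atom] - pos[:, bref], axis=-1)
        if aref is not None:
            out[:, k, 1] = _angles_batch(pos[:, atom], pos[:, bref], pos[:, aref])
        if dref is not None:
            out[:, k, 2] = _dihedrals_batch(
                pos[:, atom], pos[:, bref], pos[:, aref], pos[:, dref]
            )
    return out[0] if squeeze else out


def to_internal(geom: MolecularGeometry | np.ndarray) -> np.ndarray:
    pos = geom.positions if isinstance(geom, MolecularGeometry) else geom
    return to_internal_batch(pos)


def rebuild_batch(internals: np.ndarray) -> np.ndarray:
    """Rebuild canonical-order Cartesians (T, 26, 3) from internals by NeRF."""
    zi = np.asarray(internals, float)
    squeeze = zi.ndim == 2
    if squeeze:
        zi = zi[None]
    t = zi.shape[0]
    pos = np.zeros((t, N_ATOMS, 3))
    for k, (atom, bref, aref, dref) in enumerate(ZMATRIX):
        if bref is None:
            pos[:, atom] = 0.0
            continue
        r = zi[:, k, 0]
        if aref is None:
            pos[:, atom] = pos[:, bref]
            pos[:, atom, 0] += r
            continue
        theta = zi[:, k, 1]
        if dref is None:
            # place in the z=0 plane at the requested angle
            u = pos[:, aref] - pos[:, bref]
            u = u / np.linalg.norm(u, axis=-1, keepdims=True)
            perp = np.zeros_like(u)
            perp[:, 0] = -u[:, 1]
            perp[:, 1] = u[:, 0]
            nrm = np.linalg.norm(perp, axis=-1, keepdims=True)
            perp = np.where(nrm > 1e-12, perp / np.maximum(nrm, 1e-12), [1.0, 0.0, 0.0])
            d = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * perp
            pos[:, atom] = pos[:, bref] + r[:, None] * d
            continue
        phi = zi[:, k, 2]
        c = pos[:, bref]
        b = pos[:, aref]
        a = pos[:, dref]
        bc = c - b
        bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
        ab = b - a
        n = np.cross(ab, bc)
        n = n / np.linalg.norm(n, axis=-1, keepdims=True)
        m = np.cross(n, bc)
        d2 = np.stack(
            [
                -r * np.cos(theta),
                r * np.sin(theta) * np.cos(phi),
                r * np.sin(theta) * np.sin(phi),
            ],
            axis=-1,
        )
        pos[:, atom] = (
            c + d2[:, 0:1] * bc + d2[:, 1:2] * m + d2[:, 2:3] * n
        )
    return pos[0] if squeeze else pos


def rebuild(internals: np.ndarray) -> np.ndarray:
    return rebuild_batch(internals)


def _wrap_pi(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def interpolate(
    internals_a: np.ndarray, internals_b: np.ndarray, lam: float | np.ndarray
) -> np.ndarray:
    """Interpolate internals a -> b; dihedrals follow the shortest arc.

    ``lam`` may be scalar or an array broadcastable to a batch axis; 0 gives
    ``a``, 1 gives ``b``.
    """
    a = np.asarray(internals_a, float)
    b = np.asarray(internals_b, float)
    lam_arr = np.asarray(lam, float)
    if lam_arr.ndim > 0:
        lam3 = lam_arr[..., None, None]
        lam2 = lam_arr[..., None]
    else:
        lam3 = lam2 = lam_arr
    out = a + lam3 * (b - a)
    delta = _wrap_pi(b[..., 2] - a[..., 2])
    out[..., 2] = a[..., 2] + lam2 * delta
    return out
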