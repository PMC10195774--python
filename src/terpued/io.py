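"""File formats: XYZ geometries/trajectories, ensemble manifests, curve CSV.

Units are fixed package-wide: Å for coordinates and distances, fs for time,
eV for energies, degrees for angles.  Curve files carry a commented header
recording the transform configuration so that analyses round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffraction import PDFCurve, ScatteringCurve, TransformConfig
from .ensemble import WavepacketEnsemble, WeightedTrajectory
from .geometry import CARBON_LABELS, MolecularGeometry
from .internal import CANONICAL_ELEMENTS, canonical_carbon_map

__all__ = [
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_label_map",
    "write_label_map",
    "save_ensemble",
    "load_ensemble",
    "write_curve_csv",
    "read_curve_csv",
]


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries file, frame and line context."""


def read_xyz(
    path: str | Path, carbon_map: Mapping[str, int] | None = None
) -> list[MolecularGeometry]:
    """Read a (possibly multi-frame) XYZ file.

    The standard dialect: an atom-count line, a free-form comment line, then
    one ``element x y z`` line per atom (Å).  ``carbon_map`` labels the
    carbons of every frame; omit it for unlabelled toy molecules.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    geoms: list[MolecularGeometry] = []
    comments: list[str] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: frame {frame}, line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise XYZParseError(
                f"{path}: frame {frame} declares {natoms} atoms but file ends after {len(body)}"
            )
        elements = []
        pos = np.empty((natoms, 3))
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: frame {frame}, line {i + 3 + k}: expected 'element x y z', got {line!r}"
                )
            elements.append(parts[0])
            try:
                pos[k] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"{path}: frame {frame}, line {i + 3 + k}: non-numeric coordinate in {line!r}"
                ) from None
        geoms.append(
            MolecularGeometry(tuple(elements), pos, dict(carbon_map or {}))
        )
        comments.append(comment)
        i += 2 + natoms
        frame += 1
    if not geoms:
        raise XYZParseError(f"{path}: no frames found")
    return geoms


def write_xyz(
    path: str | Path,
    geometries: MolecularGeometry | Sequence[MolecularGeometry],
    comments: str | Sequence[str] = "",
) -> None:
    """Write one or more geometries as a multi-frame XYZ file (Å)."""
    if isinstance(geometries, MolecularGeometry):
        geometries = [geometries]
    if isinstance(comments, str):
        comments = [comments] * len(geometries)
    with open(path, "w") as fh:
        for geom, comment in zip(geometries, comments):
            fh.write(f"{geom.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(geom.elements, geom.positions):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def write_label_map(path: str | Path, carbon_map: Mapping[str, int]) -> None:
    """Sidecar label file: one ``label index`` (0-based) pair per line."""
    with open(path, "w") as fh:
        fh.write("# carbon label -> 0-based atom index\n")
        for label in sorted(carbon_map, key=lambda l: int(l[1:])):
            fh.write(f"{label} {carbon_map[label]}\n")


def read_label_map(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, idx = line.split()
        out[label] = int(idx)
    return out


# --------------------------------------------------------------------------
# Ensemble manifest
# --------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("trajectory_id", "time_fs", "state", "weight", "xyz_path")


def save_ensemble(ens: WavepacketEnsemble, directory: str | Path) -> Path:
    """Write an ensemble as manifest CSV + one multi-frame XYZ per trajectory.

    Returns the manifest path.  A sidecar ``labels.txt`` records the carbon
    label map shared by all trajectories.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, traj in enumerate(ens.trajectories):
        xyz_name = f"traj_{i:04d}.xyz"
        comments = [
            f"t_fs={t:.3f} state=S{s} weight={w:.8g}"
            for t, s, w in zip(traj.times, traj.states, traj.weights)
        ]
        write_xyz(directory / xyz_name, list(_traj_geoms(traj)), comments)
        for t, s, w in zip(traj.times, traj.states, traj.weights):
            rows.append((i, float(t), f"S{int(s)}", float(w), xyz_name))
    df = pd.DataFrame(rows, columns=list(_MANIFEST_COLUMNS))
    manifest = directory / "manifest.csv"
    df.to_csv(manifest, index=False)
    write_label_map(directory / "labels.txt", dict(ens.trajectories[0].template.carbon_map))
    return manifest


def _traj_geoms(traj: WeightedTrajectory):
    for i in range(traj.n_frames):
        yield traj.geometry_at(i)


def load_ensemble(manifest_path: str | Path) -> WavepacketEnsemble:
    """Load an ensemble written by :func:`save_ensemble`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    labels_file = directory / "labels.txt"
    carbon_map = read_label_map(labels_file) if labels_file.exists() else {}
    trajectories = []
    time_grid = None
    for _, group in df.groupby("trajectory_id", sort=True):
        group = group.sort_values("time_fs")
        xyz = directory / group["xyz_path"].iloc[0]
        geoms = read_xyz(xyz, carbon_map)
        times = group["time_fs"].to_numpy(float)
        if len(geoms) != len(times):
            raise ValueError(f"{xyz}: {len(geoms)} frames but {len(times)} manifest rows")
        states = np.array([int(s.lstrip("S")) for s in group["state"]], np.int8)
        weights = group["weight"].to_numpy(float)
        template = geoms[0]
        positions = np.stack([g.positions for g in geoms])
        trajectories.append(
            WeightedTrajectory(times, positions, states, weights, template)
        )
        time_grid = times
    return WavepacketEnsemble(trajectories, time_grid)


# --------------------------------------------------------------------------
# Curve CSV with configuration header
# --------------------------------------------------------------------------


def write_curve_csv(
    path: str | Path,
    x: np.ndarray,
    y: np.ndarray,
    x_name: str,
    y_name: str,
    header: Mapping[str, object] | None = None,
) -> None:
    """Two-column CSV with a commented JSON header (units + configuration)."""
    with open(path, "w") as fh:
        if header:
            fh.write("# " + json.dumps(dict(header), sort_keys=True) + "\n")
        fh.write(f"{x_name},{y_name}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{float(xi)!r},{float(yi)!r}\n")


def read_curve_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a curve CSV; returns (x, y, header_dict)."""
    lines = Path(path).read_text().splitlines()
    header: dict = {}
    start = 0
    if lines and lines[0].startswith("#"):
        header = json.loads(lines[0][1:].strip())
        start = 1
    data = [l.split(",") for l in lines[start + 1 :] if l.strip()]
    x = np.array([float(a) for a, _ in data])
    y = np.array([float(b) for _, b in data])
    return x, y, header
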