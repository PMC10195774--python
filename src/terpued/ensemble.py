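"""Weighted, state-labelled trajectory ensembles on a common time grid.

A :class:`WavepacketEnsemble` is a discrete stand-in for a frozen-Gaussian
wavepacket expansion: each trajectory carries a population-like weight time
series and an electronic-state label (S0/S1) per frame.  The module provides
state population traces, weighted coordinate expectation values, 2-D Gaussian
kernel density projections, and the open/closed branching classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .geometry import MolecularGeometry, pair_distance

__all__ = [
    "S0",
    "S1",
    "TrajectoryFrame",
    "WeightedTrajectory",
    "WavepacketEnsemble",
    "DensityGrid",
    "population_trace",
    "expectation",
    "density_projection_2d",
    "branching_fraction",
]

S0: int = 0
S1: int = 1
_STATE_NAMES = {"S0": S0, "S1": S1, S0: S0, S1: S1}


def _state_code(state: int | str) -> int:
    try:
        return _STATE_NAMES[state]
    except KeyError:
        raise ValueError(f"unknown electronic state {state!r}") from None


@dataclass(frozen=True)
class TrajectoryFrame:
    """A single time slice of one trajectory."""

    time: float
    geometry: MolecularGeometry
    state: int


@dataclass(frozen=True)
class WeightedTrajectory:
    """One trajectory: frames on a time grid plus a weight time series.

    ``positions`` has shape (T, n_atoms, 3); ``states`` and ``weights`` have
    shape (T,).  ``template`` supplies elements and the carbon label map.
    """

    times: np.ndarray
    positions: np.ndarray
    states: np.ndarray
    weights: np.ndarray
    template: MolecularGeometry

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        pos = np.asarray(self.positions, float)
        st = np.asarray(self.states, np.int8)
        w = np.asarray(self.weights, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if pos.shape != (t.size, self.template.n_atoms, 3):
            raise ValueError(f"positions shape {pos.shape} inconsistent with grid")
        if st.shape != t.shape or w.shape != t.shape:
            raise ValueError("states/weights must be defined on the time grid")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        for name, val in (("times", t), ("positions", pos), ("states", st), ("weights", w)):
            object.__setattr__(self, name, val)

    @property
    def n_frames(self) -> int:
        return self.times.size

    def geometry_at(self, idx: int) -> MolecularGeometry:
        return self.template.with_positions(self.positions[idx])

    def frames(self) -> Iterator[TrajectoryFrame]:
        for i in range(self.n_frames):
            yield TrajectoryFrame(float(self.times[i]), self.geometry_at(i), int(self.states[i]))

    def resampled(self, time_grid: np.ndarray) -> "WeightedTrajectory":
        """Piecewise-linear resampling of positions/weights to a new grid.

        State labels are carried by the previous native frame (a hop happens
        between frames; no fractional states).
        """
        tg = np.asarray(time_grid, float)
        if tg[0] < self.times[0] - 1e-9 or tg[-1] > self.times[-1] + 1e-9:
            raise ValueError("target grid outside the native time span")
        flat = self.positions.reshape(self.n_frames, -1)
        interp = np.empty((tg.size, flat.shape[1]))
        for j in range(flat.shape[1]):
            interp[:, j] = np.interp(tg, self.times, flat[:, j])
        w = np.interp(tg, self.times, self.weights)
        idx = np.clip(np.searchsorted(self.times, tg + 1e-9) - 1, 0, self.n_frames - 1)
        return WeightedTrajectory(
            times=tg,
            positions=interp.reshape(tg.size, -1, 3),
            states=self.states[idx],
            weights=w,
            template=self.template,
        )


@dataclass(frozen=True)
class WavepacketEnsemble:
    """Trajectories sharing a common time grid; weights sum to 1 per time."""

    trajectories: Sequence[WeightedTrajectory]
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        tg = np.asarray(self.time_grid, float)
        object.__setattr__(self, "time_grid", tg)
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        if not self.trajectories:
            raise ValueError("empty ensemble")
        for traj in self.trajectories:
            if traj.times.shape != tg.shape or not np.allclose(traj.times, tg):
                raise ValueError("all trajectories must share the ensemble time grid")
        total = self.weight_matrix().sum(axis=0)
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("trajectory weights must sum to 1 at every time")

    @property
    def n_traj(self) -> int:
        return len(self.trajectories)

    def weight_matrix(self) -> np.ndarray:
        return np.stack([t.weights for t in self.trajectories])

    def state_matrix(self) -> np.ndarray:
        return np.stack([t.states for t in self.trajectories])

    def time_index(self, t: float) -> int:
        idx = int(np.argmin(np.abs(self.time_grid - t)))
        return idx

    def geometries_at(
        self, t: float, state: int | str | None = None
    ) -> tuple[list[MolecularGeometry], np.ndarray]:
        """Geometries and weights of all (optionally state-filtered) frames at ~t."""
        idx = self.time_index(t)
        geoms, w = [], []
        code = None if state is None else _state_code(state)
        for traj in self.trajectories:
            if code is not None and int(traj.states[idx]) != code:
                continue
            geoms.append(traj.geometry_at(idx))
            w.append(float(traj.weights[idx]))
        return geoms, np.asarray(w)

    def subset(self, indices: Sequence[int]) -> "WavepacketEnsemble":
        """Sub-ensemble of the given trajectories, weights renormalized."""
        chosen = [self.trajectories[i] for i in indices]
        total = np.sum([t.weights for t in chosen], axis=0)
        if np.any(total <= 0):
            raise ValueError("subset has zero weight at some time")
        renorm = [
            WeightedTrajectory(
                t.times, t.positions, t.states, t.weights / total, t.template
            )
            for t in chosen
        ]
        return WavepacketEnsemble(renorm, self.time_grid)


def population_trace(ens: WavepacketEnsemble, state: int | str) -> np.ndarray:
    """Fractional population of one electronic state per time point."""
    code = _state_code(state)
    w = ens.weight_matrix()
    mask = ens.state_matrix() == code
    return (w * mask).sum(axis=0)


def expectation(
    ens: WavepacketEnsemble,
    coord: Callable[[MolecularGeometry], float],
    state: int | str | None = None,
) -> np.ma.MaskedArray:
    """Weight-normalized expectation value of a coordinate over time.

    Points where the state-filtered population vanishes are masked rather
    than raising.
    """
    code = None if state is None else _state_code(state)
    w = ens.weight_matrix().copy()
    if code is not None:
        w *= ens.state_matrix() == code
    values = np.empty_like(w)
    for i, traj in enumerate(ens.trajectories):
        for k in range(traj.n_frames):
            if w[i, k] > 0:
                values[i, k] = coord(traj.geometry_at(k))
            else:
                values[i, k] = 0.0
    wsum = w.sum(axis=0)
    masked = wsum <= 0
    safe = np.where(masked, 1.0, wsum)
    mean = (w * values).sum(axis=0) / safe
    return np.ma.MaskedArray(mean, mask=masked)


@dataclass(frozen=True)
class DensityGrid:
    """A 2-D kernel density on a rectangular grid."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.y, axis=1), self.x))

    def marginal_x(self) -> np.ndarray:
        return np.trapezoid(self.density, self.y, axis=1)


def density_projection_2d(
    ens: WavepacketEnsemble,
    coord_x: Callable[[MolecularGeometry], float],
    coord_y: Callable[[MolecularGeometry], float],
    t: float,
    kernel_widths: tuple[float, float] = (0.05, 2.0),
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    state: int | str = S1,
) -> DensityGrid:
    """Gaussian-kernel density of state-filtered frames at time t.

    Frame weights act as masses, so the density integrates to the filtered
    state population at t.  Default kernel widths (0.05 Å, 2 deg) stand in
    for the unspecified frozen widths of the underlying wavepacket basis.
    """
    sx, sy = kernel_widths
    if sx <= 0 or sy <= 0:
        raise ValueError("kernel widths must be positive")
    geoms, w = ens.geometries_at(t, state)
    if grid is None:
        if geoms:
            xs = np.array([coord_x(g) for g in geoms])
            ys = np.array([coord_y(g) for g in geoms])
            gx = np.linspace(xs.min() - 4 * sx, xs.max() + 4 * sx, 201)
            gy = np.linspace(ys.min() - 4 * sy, ys.max() + 4 * sy, 201)
        else:
            gx = np.linspace(0, 1, 2)
            gy = np.linspace(0, 1, 2)
    else:
        gx, gy = (np.asarray(g, float) for g in grid)
    dens = np.zeros((gx.size, gy.size))
    if geoms:
        xs = np.array([coord_x(g) for g in geoms])
        ys = np.array([coord_y(g) for g in geoms])
        kx = np.exp(-((gx[None, :] - xs[:, None]) ** 2) / (2 * sx**2)) / (
            sx * np.sqrt(2 * np.pi)
        )
        ky = np.exp(-((gy[None, :] - ys[:, None]) ** 2) / (2 * sy**2)) / (
            sy * np.sqrt(2 * np.pi)
        )
        dens = np.einsum("f,fx,fy->xy", w, kx, ky)
    return DensityGrid(gx, gy, dens)


def branching_fraction(
    ens: WavepacketEnsemble,
    open_threshold: float = 2.0,
    at_time: float | None = None,
    mode: str = "population",
) -> float:
    """Fraction of S0 population (or trajectories) with an opened ring.

    A frame counts as ring-open when its C3-C4 distance exceeds
    ``open_threshold`` (default 2.0 Å, past the ring-open CI region).
    Classification is done at ``at_time`` (default: the final grid time)
    only, avoiding transient-recrossing ambiguity.
    """
    if mode not in ("population", "trajectory"):
        raise ValueError("mode must be 'population' or 'trajectory'")
    t = float(ens.time_grid[-1]) if at_time is None else at_time
    idx = ens.time_index(t)
    num = 0.0
    den = 0.0
    for traj in ens.trajectories:
        if int(traj.states[idx]) != S0:
            continue
        w = float(traj.weights[idx]) if mode == "population" else 1.0
        den += w
        if pair_distance(traj.geometry_at(idx), "C3", "C4") > open_threshold:
            num += w
    if den <= 0:
        raise ValueError(f"no S0 population at t = {t} fs")
    return num / den
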