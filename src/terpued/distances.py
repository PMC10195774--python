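"""Carbon-carbon distance distribution functions (ccDDF) by coordination sphere.

The ccDDF is the geometric histogram underlying the PDF: every unordered
carbon pair contributes its ensemble-weighted distance to the histogram of
its coordination sphere (shortest bond-path length in the *fixed* reactant
topology).  Third-sphere pairs additionally carry a cis/trans sublabel, which
is assigned once on a reference reactant geometry and then propagated —
the labels describe reactant-frame conformations, not per-frame dihedrals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .geometry import (
    CARBON_LABELS,
    BondTopology,
    MolecularGeometry,
    cis_trans_label,
    coordination_sphere,
    pair_distance,
)

__all__ = [
    "DistanceDistribution",
    "default_bins",
    "ccddf",
    "delta_ccddf",
    "histogram_extrema",
    "sphere_gap_minimum",
]


def default_bins(r_lo: float = 1.0, r_hi: float = 8.0, width: float = 0.05) -> np.ndarray:
    """Default histogram bin edges: 0.05 Å bins over [1, 8] Å."""
    n = int(round((r_hi - r_lo) / width))
    return r_lo + width * np.arange(n + 1)


@dataclass(frozen=True)
class DistanceDistribution:
    """Weighted per-sphere C-C distance histograms on common bin edges.

    ``sphere_hist[k]`` holds the histogram of sphere-``k`` pairs;
    ``sphere3_split`` holds the cis/trans decomposition of sphere 3.  With
    weights normalized to 1, each sphere integrates to its pair count.
    """

    bin_edges: np.ndarray
    sphere_hist: Mapping[int, np.ndarray]
    sphere3_split: Mapping[str, np.ndarray]

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def spheres(self) -> tuple[int, ...]:
        return tuple(sorted(self.sphere_hist))

    def total(self) -> np.ndarray:
        return np.sum([h for h in self.sphere_hist.values()], axis=0)


def _pair_spheres(topology: BondTopology) -> dict[tuple[str, str], int]:
    return {
        (a, b): coordination_sphere(topology, a, b)
        for a, b in combinations(CARBON_LABELS, 2)
    }


def ccddf(
    geometries: Sequence[MolecularGeometry],
    weights: Sequence[float] | None = None,
    topology: BondTopology | None = None,
    bins: np.ndarray | None = None,
    reference: MolecularGeometry | None = None,
) -> DistanceDistribution:
    """Coordination-sphere-partitioned C-C distance histogram of an ensemble.

    ``reference`` supplies the geometry on which sphere-3 cis/trans sublabels
    are evaluated (default: the first geometry of the ensemble).
    """
    geometries = list(geometries)
    if not geometries:
        raise ValueError("empty ensemble")
    topology = topology or BondTopology.reactant()
    edges = np.asarray(bins if bins is not None else default_bins(), float)
    if weights is None:
        w = np.full(len(geometries), 1.0 / len(geometries))
    else:
        w = np.asarray(weights, float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = w / w.sum()
    reference = reference or geometries[0]

    spheres = _pair_spheres(topology)
    sublabel = {
        pair: cis_trans_label(reference, topology, *pair)
        for pair, k in spheres.items()
        if k == 3
    }

    nbins = len(edges) - 1
    hist: dict[int, np.ndarray] = {}
    split = {"cis": np.zeros(nbins), "trans": np.zeros(nbins)}
    for pair, k in spheres.items():
        d = np.array([pair_distance(g, *pair) for g in geometries])
        h, _ = np.histogram(d, bins=edges, weights=w)
        hist[k] = hist.get(k, np.zeros(nbins)) + h
        if k == 3:
            split[sublabel[pair]] += h
    return DistanceDistribution(edges, hist, split)


def delta_ccddf(
    at_t: DistanceDistribution, reference: DistanceDistribution
) -> DistanceDistribution:
    """Binwise difference of two ccDDFs; each sphere sums to ~0 (pair count conserved)."""
    if not np.array_equal(at_t.bin_edges, reference.bin_edges):
        raise ValueError("bin edges differ")
    spheres = set(at_t.sphere_hist) | set(reference.sphere_hist)
    nbins = len(at_t.bin_edges) - 1
    zero = np.zeros(nbins)
    hist = {
        k: at_t.sphere_hist.get(k, zero) - reference.sphere_hist.get(k, zero)
        for k in spheres
    }
    split = {
        lbl: at_t.sphere3_split.get(lbl, zero) - reference.sphere3_split.get(lbl, zero)
        for lbl in ("cis", "trans")
    }
    return DistanceDistribution(at_t.bin_edges, hist, split)


def _smoothed(dist: DistanceDistribution, sphere: int, sigma_bins: float) -> np.ndarray:
    if sphere not in dist.sphere_hist:
        raise ValueError(f"sphere {sphere} not present")
    return gaussian_filter1d(dist.sphere_hist[sphere].astype(float), sigma_bins)


def histogram_extrema(
    dist: DistanceDistribution,
    sphere: int,
    sigma_bins: float = 2.0,
    min_fraction: float = 0.05,
) -> list[tuple[float, str]]:
    """Local maxima, and the interior minimum between the two largest maxima.

    Extrema are located on a Gaussian-smoothed histogram (kernel sigma in
    bins) and reported at bin-center resolution.  Maxima below
    ``min_fraction`` of the tallest are ignored.  When a flat minimum plateau
    separates the maxima, its center is reported.
    """
    v = _smoothed(dist, sphere, sigma_bins)
    centers = dist.bin_centers
    thr = min_fraction * v.max()
    maxima: list[int] = [
        i
        for i in range(1, len(v) - 1)
        if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > thr
    ]
    out: list[tuple[float, str]] = [(float(centers[i]), "max") for i in maxima]
    if len(maxima) >= 2:
        top2 = sorted(sorted(maxima, key=lambda i: -v[i])[:2])
        lo, hi = top2
        seg = v[lo : hi + 1]
        vmin = seg.min()
        flat = np.flatnonzero(np.isclose(seg, vmin, rtol=0, atol=1e-12 * max(v.max(), 1)))
        imin = lo + int(round(flat.mean()))
        out.append((float(centers[imin]), "min"))
    out.sort()
    return out


def sphere_gap_minimum(
    dist: DistanceDistribution, sphere: int = 3, sigma_bins: float = 2.0
) -> float:
    """Location (Å) of the interior minimum between the two largest maxima."""
    ext = histogram_extrema(dist, sphere, sigma_bins)
    mins = [loc for loc, kind in ext if kind == "min"]
    if not mins:
        raise ValueError(f"sphere {sphere} histogram has fewer than 2 maxima")
    return mins[0]
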