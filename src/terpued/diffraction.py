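"""Independent-atom-model (IAM) forward simulation of gas-phase electron diffraction.

The observable is the modified molecular scattering intensity

    sM(s) = s * I_mol(s) / I_at(s),

with the rotationally averaged Debye molecular term

    I_mol(s) = sum_{i != j} f_i(s) f_j(s) sin(s r_ij) / (s r_ij),

and the atomic background I_at(s) = sum_i f_i(s)^2.  Real-space pair
distribution functions are obtained by a damped sine transform

    PDF(r) = int sM(s) sin(s r) exp(-alpha s^2) ds,

evaluated by the trapezoidal rule on the configured s-window.  Difference
PDFs between a pumped ensemble and the unpumped reference are scaled by the
experimental excitation fraction.

Elastic electron scattering amplitudes use the sum-of-Gaussians
parameterization of Peng, Ren, Dudarev & Whelan (Acta Cryst. A52, 257, 1996);
their tabulation is in the crystallographic variable q = s / (4 pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .geometry import MolecularGeometry

__all__ = [
    "PENG_COEFFICIENTS",
    "electron_form_factor",
    "TransformConfig",
    "ScatteringCurve",
    "PDFCurve",
    "compute_sm",
    "pdf_from_sm",
    "delta_pdf",
]

#: Peng et al. (1996) 5-Gaussian fits f(q) = sum a_i exp(-b_i q^2), q = sin(theta)/lambda.
PENG_COEFFICIENTS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "H": (
        (0.0349, 0.1201, 0.1970, 0.0573, 0.1195),
        (0.5347, 3.5867, 12.3471, 83.7881, 166.0798),
    ),
    "C": (
        (0.0893, 0.2563, 0.7570, 1.0487, 0.3575),
        (0.2465, 1.7100, 6.4094, 18.6113, 50.2523),
    ),
}


def electron_form_factor(element: str, s: np.ndarray) -> np.ndarray:
    """Elastic electron scattering amplitude f(s) (Å) at momentum transfer s (Å^-1)."""
    try:
        a, b = PENG_COEFFICIENTS[element]
    except KeyError:
        raise ValueError(f"no form factor tabulated for element {element!r}") from None
    q2 = (np.asarray(s, float) / (4.0 * np.pi)) ** 2
    return sum(ai * np.exp(-bi * q2) for ai, bi in zip(a, b))


@dataclass(frozen=True)
class TransformConfig:
    """s-window, damping and r-grid of the sine transform.

    The default damping constant is chosen so that exp(-alpha s_max^2) = 0.1,
    the usual compromise between real-space resolution and truncation ripple.
    """

    s_min: float = 0.5
    s_max: float = 10.0
    ds: float = 0.02
    damping_alpha: float | None = None
    r_max: float = 8.0
    dr: float = 0.01

    def __post_init__(self) -> None:
        if self.s_min <= 0 or self.s_max <= self.s_min or self.ds <= 0:
            raise ValueError("require 0 < s_min < s_max and ds > 0")
        if self.damping_alpha is None:
            object.__setattr__(
                self, "damping_alpha", float(np.log(10.0) / self.s_max**2)
            )

    @property
    def s_grid(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.ds)) + 1
        return self.s_min + self.ds * np.arange(n)

    @property
    def r_grid(self) -> np.ndarray:
        n = int(round(self.r_max / self.dr)) + 1
        return self.dr * np.arange(n)


@dataclass(frozen=True)
class ScatteringCurve:
    """sM(s) on an ascending momentum-transfer grid (Å^-1)."""

    s_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_grid, float)
        v = np.asarray(self.values, float)
        if s.ndim != 1 or s.shape != v.shape:
            raise ValueError("s_grid and values must be equal-length 1-D arrays")
        if np.any(np.diff(s) <= 0):
            raise ValueError("s_grid must be strictly ascending")
        object.__setattr__(self, "s_grid", s)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PDFCurve:
    """PDF(r) or ΔPDF(r) on an ascending real-space grid (Å)."""

    r_grid: np.ndarray
    values: np.ndarray
    label: str = "static"
    delay_fs: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_grid, float)
        v = np.asarray(self.values, float)
        if r.ndim != 1 or r.shape != v.shape:
            raise ValueError("r_grid and values must be equal-length 1-D arrays")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r_grid must be strictly ascending")
        if self.label not in ("static", "delta"):
            raise ValueError("label must be 'static' or 'delta'")
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "values", v)

    def first_maximum(self) -> float:
        """Location (Å) of the first interior local maximum."""
        v = self.values
        for i in range(1, len(v) - 1):
            if v[i] > v[i - 1] and v[i] >= v[i + 1]:
                return float(self.r_grid[i])
        raise ValueError("no interior maximum")

    def local_maxima(self, min_fraction: float = 0.05) -> list[float]:
        """Interior local maxima above ``min_fraction`` of the global maximum."""
        v = self.values
        thr = min_fraction * float(v.max())
        out = []
        for i in range(1, len(v) - 1):
            if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > thr:
                out.append(float(self.r_grid[i]))
        return out


def _stack_positions(geometries: Sequence[MolecularGeometry]) -> np.ndarray:
    first = geometries[0]
    elements = first.elements
    pos = np.empty((len(geometries), first.n_atoms, 3))
    for g, geom in enumerate(geometries):
        if geom.elements != elements:
            raise ValueError("all geometries must share one atom list/order")
        pos[g] = geom.positions
    return pos


def compute_sm(
    geometries: Sequence[MolecularGeometry],
    weights: Sequence[float] | None = None,
    s_grid: np.ndarray | None = None,
    *,
    config: TransformConfig | None = None,
    chunk: int = 50_000,
) -> ScatteringCurve:
    """Weight-averaged IAM sM(s) of an ensemble of geometries.

    Weights are normalized internally, so the result is invariant under a
    uniform rescaling of the weights.
    """
    geometries = list(geometries)
    if not geometries:
        raise ValueError("empty geometry list")
    if s_grid is None:
        s_grid = (config or TransformConfig()).s_grid
    s = np.asarray(s_grid, float)
    if weights is None:
        w = np.full(len(geometries), 1.0 / len(geometries))
    else:
        w = np.asarray(weights, float)
        if w.shape != (len(geometries),) or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per geometry")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive number")
        w = w / total

    elements = geometries[0].elements
    n = len(elements)
    f_by_el = {el: electron_form_factor(el, s) for el in set(elements)}
    i_at = np.zeros_like(s)
    for el in elements:
        i_at += f_by_el[el] ** 2
    if n < 2:
        return ScatteringCurve(s, np.zeros_like(s))

    pos = _stack_positions(geometries)
    iu, ju = np.triu_indices(n, k=1)
    # pairwise distances for all geometries: (G, P)
    diff = pos[:, iu] - pos[:, ju]
    dists = np.linalg.norm(diff, axis=-1)
    # form-factor product per pair: (P, S)
    f_i = np.stack([f_by_el[elements[i]] for i in iu])
    f_j = np.stack([f_by_el[elements[j]] for j in ju])
    f_pair = f_i * f_j

    i_mol = np.zeros_like(s)
    r_flat = dists.reshape(-1)
    w_flat = np.repeat(w, len(iu))
    fp_flat_idx = np.tile(np.arange(len(iu)), len(geometries))
    for start in range(0, r_flat.size, chunk):
        sl = slice(start, start + chunk)
        sr = np.outer(r_flat[sl], s)
        kern = np.sinc(sr / np.pi)  # sin(sr)/(sr), safe at sr=0
        contrib = w_flat[sl, None] * f_pair[fp_flat_idx[sl]] * kern
        i_mol += 2.0 * contrib.sum(axis=0)
    return ScatteringCurve(s, s * i_mol / i_at)


def pdf_from_sm(
    curve: ScatteringCurve,
    r_grid: np.ndarray | None = None,
    damping_alpha: float | None = None,
    *,
    config: TransformConfig | None = None,
    label: str = "static",
    delay_fs: float | None = None,
) -> PDFCurve:
    """Damped sine transform of sM(s); linear in the input curve."""
    cfg = config or TransformConfig()
    r = np.asarray(r_grid if r_grid is not None else cfg.r_grid, float)
    alpha = cfg.damping_alpha if damping_alpha is None else float(damping_alpha)
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_grid must be strictly ascending")
    s = curve.s_grid
    damped = curve.values * np.exp(-alpha * s**2)
    integrand = damped[None, :] * np.sin(np.outer(r, s))
    values = np.trapezoid(integrand, s, axis=1)
    return PDFCurve(r, values, label=label, delay_fs=delay_fs)


def delta_pdf(
    ensemble_at_t: tuple[Sequence[MolecularGeometry], Sequence[float] | None],
    reference: tuple[Sequence[MolecularGeometry], Sequence[float] | None],
    excitation_fraction: float = 0.0156,
    *,
    config: TransformConfig | None = None,
    delay_fs: float | None = None,
) -> PDFCurve:
    """ΔPDF(r) = excitation_fraction * (PDF_excited - PDF_reference).

    The default excitation fraction (1.56 %) emulates the experimental pump
    excitation probability.
    """
    if not 0.0 < excitation_fraction <= 1.0:
        raise ValueError("excitation_fraction must be in (0, 1]")
    cfg = config or TransformConfig()
    geoms_t, w_t = ensemble_at_t
    geoms_r, w_r = reference
    sm_t = compute_sm(geoms_t, w_t, cfg.s_grid)
    sm_r = compute_sm(geoms_r, w_r, cfg.s_grid)
    diff = ScatteringCurve(cfg.s_grid, sm_t.values - sm_r.values)
    pdf = pdf_from_sm(diff, config=cfg, label="delta", delay_fs=delay_fs)
    return PDFCurve(
        pdf.r_grid,
        excitation_fraction * pdf.values,
        label="delta",
        delay_fs=delay_fs,
    )
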