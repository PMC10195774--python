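"""End-to-end analysis: ensemble -> observables -> region kinetics -> report.

Stage order mirrors the experimental analysis: static PDF and ccDDF from the
unpumped reference, delay-dependent ΔPDFs from the excited ensemble, region
integration (α/β/γ), instrument-response convolution, error-function onset
fits with trajectory-bootstrap uncertainties, and the mechanistic summary
numbers (ring-opening branching fraction, reporter-distance dip time).

Region traces are linear in the per-trajectory scattering curves, so the
bootstrap resamples a precomputed (trajectory x delay x region) tensor
instead of re-running the forward model.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import PipelineConfig, config_hash, save_config
from .diffraction import (
    PDFCurve,
    ScatteringCurve,
    TransformConfig,
    compute_sm,
    electron_form_factor,
    pdf_from_sm,
)
from .distances import ccddf, histogram_extrema, sphere_gap_minimum
from .ensemble import S1, WavepacketEnsemble, branching_fraction, expectation, population_trace
from .geometry import pair_distance_coordinate
from .io import load_ensemble, save_ensemble, write_curve_csv
from .kinetics import (
    BootstrapResult,
    OnsetFit,
    RegionDefinition,
    convolve_irf,
    fit_erf_onset,
)
from .surrogate import generate_ensemble

__all__ = ["PipelineStageError", "PipelineReport", "run_pipeline", "sm_matrix", "region_operator"]

logger = logging.getLogger("terpued.pipeline")


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


def sm_matrix(geometries: Sequence, s_grid: np.ndarray) -> np.ndarray:
    """Per-geometry sM(s) rows, shape (n_geometries, n_s).

    ``compute_sm`` with weights w equals ``w_normalized @ sm_matrix``; keeping
    the per-geometry rows makes trajectory bootstraps a reweighting.
    """
    s = np.asarray(s_grid, float)
    elements = geometries[0].elements
    n = len(elements)
    f_by_el = {el: electron_form_factor(el, s) for el in set(elements)}
    i_at = np.zeros_like(s)
    for el in elements:
        i_at += f_by_el[el] ** 2
    out = np.zeros((len(geometries), s.size))
    if n < 2:
        return out
    iu, ju = np.triu_indices(n, k=1)
    f_pair = np.stack([f_by_el[elements[i]] for i in iu]) * np.stack(
        [f_by_el[elements[j]] for j in ju]
    )
    for g, geom in enumerate(geometries):
        if geom.elements != elements:
            raise ValueError("all geometries must share one atom list/order")
        d = np.linalg.norm(geom.positions[iu] - geom.positions[ju], axis=-1)
        sr = np.outer(d, s)
        i_mol = 2.0 * (f_pair * np.sinc(sr / np.pi)).sum(axis=0)
        out[g] = s * i_mol / i_at
    return out


def region_operator(cfg: TransformConfig, region: RegionDefinition) -> np.ndarray:
    """Vector t such that ``sM . t`` equals the region integral of the PDF.

    Composes the damped sine transform with the trapezoidal region integral;
    exactly consistent with ``pdf_from_sm`` followed by ``integrate_region``.
    """
    s = cfg.s_grid
    r = cfg.r_grid
    if region.r_lo < r[0] - 1e-12 or region.r_hi > r[-1] + 1e-12:
        raise ValueError(
            f"region {region.name} [{region.r_lo}, {region.r_hi}] outside r-grid"
        )
    mask = (r >= region.r_lo - 1e-12) & (r <= region.r_hi + 1e-12)
    r_in = r[mask]
    # trapezoid weights over the region r-points
    wr = np.zeros(r_in.size)
    dr = np.diff(r_in)
    wr[:-1] += 0.5 * dr
    wr[1:] += 0.5 * dr
    # trapezoid weights over s
    ws = np.zeros(s.size)
    dsteps = np.diff(s)
    ws[:-1] += 0.5 * dsteps
    ws[1:] += 0.5 * dsteps
    damp = np.exp(-cfg.damping_alpha * s**2)
    return damp * ws * (np.sin(np.outer(s, r_in)) @ wr)


@dataclass(frozen=True)
class PipelineReport:
    """Numbers and artifacts of one pipeline run."""

    config_digest: str
    seed: int
    n_traj: int
    delays_fs: np.ndarray
    region_traces: Mapping[str, np.ndarray]
    onset_fits: Mapping[str, OnsetFit]
    onset_bootstrap: Mapping[str, BootstrapResult]
    branching: BootstrapResult
    static_pdf_maxima: tuple[float, ...]
    ccddf3_extrema: tuple[tuple[float, str], ...]
    ccddf3_gap_min: float
    c3c10_dip_fs: float
    c3c10_s1_trace: np.ndarray
    time_grid: np.ndarray

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "n_traj": self.n_traj,
            "onset_fits": {
                name: asdict(fit) | {"stderr": dict(fit.stderr)}
                for name, fit in self.onset_fits.items()
            },
            "onset_bootstrap": {
                name: asdict(b) for name, b in self.onset_bootstrap.items()
            },
            "branching": asdict(self.branching),
            "static_pdf_maxima_A": list(self.static_pdf_maxima),
            "ccddf3_extrema": [[loc, kind] for loc, kind in self.ccddf3_extrema],
            "ccddf3_gap_min_A": self.ccddf3_gap_min,
            "c3c10_dip_fs": self.c3c10_dip_fs,
        }


def _quadratic_min(t: np.ndarray, v: np.ndarray) -> float:
    """Sub-grid minimum location by parabola through the argmin and neighbors."""
    i = int(np.argmin(v))
    if i == 0 or i == v.size - 1:
        return float(t[i])
    t0, t1, t2 = t[i - 1 : i + 2]
    v0, v1, v2 = v[i - 1 : i + 2]
    denom = (v0 - 2 * v1 + v2)
    if abs(denom) < 1e-15:
        return float(t1)
    dt = t1 - t0
    return float(t1 + 0.5 * dt * (v0 - v2) / denom)


def dip_time(ens: WavepacketEnsemble, min_population: float = 0.1) -> float:
    """Time (fs) of the minimum of the S1-state C3..C10 expectation value.

    Only times with meaningful S1 population enter; the minimum is refined to
    sub-grid resolution by a local parabola.
    """
    trace = expectation(ens, pair_distance_coordinate("C3", "C10"), state=S1)
    pop = population_trace(ens, S1)
    ok = (~trace.mask) & (pop >= min_population)
    if ok.sum() < 3:
        raise ValueError("insufficient S1 population for a dip fit")
    t = ens.time_grid[ok]
    v = np.asarray(trace)[ok]
    return _quadratic_min(t, v)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = _time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.2f s", name, _time.perf_counter() - t0)
            return result

        return wrapped

    return deco


@_stage("ensemble")
def _obtain_ensemble(config: PipelineConfig) -> WavepacketEnsemble:
    if config.manifest is not None:
        ens = load_ensemble(config.manifest)
        logger.info("loaded %d trajectories from %s", ens.n_traj, config.manifest)
        return ens
    params = config.surrogate
    if config.seed != params.seed:
        from dataclasses import replace

        params = replace(params, seed=config.seed)
    ens = generate_ensemble(params)
    logger.info("generated %d surrogate trajectories", ens.n_traj)
    return ens


@_stage("static")
def _static_observables(ens: WavepacketEnsemble, config: PipelineConfig):
    ref_geoms, ref_w = ens.geometries_at(float(ens.time_grid[0]))
    sm_ref = compute_sm(ref_geoms, ref_w, config.transform.s_grid)
    pdf_ref = pdf_from_sm(sm_ref, config=config.transform)
    maxima = tuple(pdf_ref.local_maxima())
    dist = ccddf(ref_geoms, ref_w)
    extrema = tuple(histogram_extrema(dist, sphere=3))
    gap = sphere_gap_minimum(dist, sphere=3)
    return ref_geoms, ref_w, pdf_ref, maxima, dist, extrema, gap


@_stage("delta_pdf")
def _region_tensor(
    ens: WavepacketEnsemble, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delays, per-trajectory region integrals (traj, delay, region), reference row."""
    cfg = config.transform
    s = cfg.s_grid
    ops = np.stack([region_operator(cfg, reg) for reg in config.regions])  # (R, S)
    span = float(ens.time_grid[-1])
    pre = -np.arange(config.delta_dt, 6 * config.irf_fwhm / 2.355 * 2, config.delta_dt)[::-1]
    post = np.arange(0.0, span + 0.5 * config.delta_dt, config.delta_dt)
    delays = np.concatenate([pre, post])

    n_traj = ens.n_traj
    tensor = np.empty((n_traj, delays.size, len(config.regions)))
    # per-trajectory reference rows (frame at t = 0)
    geoms0 = [traj.geometry_at(0) for traj in ens.trajectories]
    m0 = sm_matrix(geoms0, s)
    r0 = m0 @ ops.T  # (traj, region)
    for d, delay in enumerate(delays):
        if delay < 0:
            tensor[:, d, :] = r0
            continue
        idx = ens.time_index(float(delay))
        geoms = [traj.geometry_at(idx) for traj in ens.trajectories]
        m = sm_matrix(geoms, s)
        tensor[:, d, :] = m @ ops.T
    ref_row = r0.mean(axis=0)  # static reference per region
    return delays, tensor, ref_row


def region_traces_from_tensor(
    tensor: np.ndarray,
    ref_row: np.ndarray,
    excitation_fraction: float,
    traj_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Region ΔPDF traces (delay, region) for a (resampled) set of trajectories."""
    sub = tensor if traj_idx is None else tensor[traj_idx]
    return excitation_fraction * (sub.mean(axis=0) - ref_row[None, :])


@_stage("fit")
def _onset_fits(
    delays: np.ndarray,
    tensor: np.ndarray,
    ref_row: np.ndarray,
    config: PipelineConfig,
) -> tuple[dict, dict, dict]:
    traces = region_traces_from_tensor(tensor, ref_row, config.excitation_fraction)
    fits: dict[str, OnsetFit] = {}
    boots: dict[str, BootstrapResult] = {}
    out_traces: dict[str, np.ndarray] = {}
    n_traj = tensor.shape[0]
    rng = np.random.default_rng(config.seed + 7)
    # erf onsets are local models of the signal rise: fit over the onset
    # window only, not the late-time plateau with its slow drifts
    window = delays <= config.fit_window_fs
    for r, region in enumerate(config.regions):
        smooth = convolve_irf(traces[:, r], config.irf_fwhm, config.delta_dt)
        out_traces[region.name] = smooth
        fits[region.name] = fit_erf_onset(delays[window], smooth[window])
        reps = np.empty(config.n_resamples)
        for b in range(config.n_resamples):
            idx = rng.integers(0, n_traj, size=n_traj)
            tr = region_traces_from_tensor(
                tensor, ref_row, config.excitation_fraction, idx
            )[:, r]
            tr = convolve_irf(tr, config.irf_fwhm, config.delta_dt)
            try:
                reps[b] = fit_erf_onset(delays[window], tr[window]).t0
            except Exception:
                reps[b] = np.nan
        good = reps[np.isfinite(reps)]
        if good.size == 0:
            good = np.array([fits[region.name].t0])
        lo, hi = np.percentile(good, [16.0, 84.0])
        boots[region.name] = BootstrapResult(
            estimate=fits[region.name].t0,
            lower=min(float(lo), fits[region.name].t0),
            upper=max(float(hi), fits[region.name].t0),
            n_resamples=config.n_resamples,
            seed=config.seed + 7,
        )
    return fits, boots, out_traces


@_stage("branching")
def _branching(ens: WavepacketEnsemble, config: PipelineConfig) -> BootstrapResult:
    indices = list(range(ens.n_traj))

    def stat(idx_list) -> float:
        return branching_fraction(
            ens.subset(list(idx_list)), open_threshold=config.open_threshold
        )

    from .kinetics import bootstrap

    return bootstrap(stat, indices, n_resamples=config.n_resamples, seed=config.seed + 11)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineReport:
    """Run every stage and (optionally) write CSV/JSON artifacts to ``outdir``."""
    digest = config_hash(config)
    logger.info("pipeline start, config %s, seed %d", digest, config.seed)
    ens = _obtain_ensemble(config)
    ref_geoms, ref_w, pdf_ref, maxima, dist, extrema, gap = _static_observables(ens, config)
    delays, tensor, ref_row = _region_tensor(ens, config)
    fits, boots, traces = _onset_fits(delays, tensor, ref_row, config)
    branch = _branching(ens, config)
    c3c10 = expectation(ens, pair_distance_coordinate("C3", "C10"), state=S1)
    dip = dip_time(ens)

    report = PipelineReport(
        config_digest=digest,
        seed=config.seed,
        n_traj=ens.n_traj,
        delays_fs=delays,
        region_traces=traces,
        onset_fits=fits,
        onset_bootstrap=boots,
        branching=branch,
        static_pdf_maxima=maxima,
        ccddf3_extrema=extrema,
        ccddf3_gap_min=gap,
        c3c10_dip_fs=dip,
        c3c10_s1_trace=np.asarray(c3c10.filled(np.nan)),
        time_grid=ens.time_grid,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = {"config": digest, "seed": config.seed, "units": "fs, Å"}
        save_config(config, outdir / "config.yaml")
        write_curve_csv(
            outdir / "static_pdf.csv",
            pdf_ref.r_grid,
            pdf_ref.values,
            "r_A",
            "pdf",
            header | {"transform": asdict(config.transform)},
        )
        for name, tr in traces.items():
            write_curve_csv(
                outdir / f"trace_{name}.csv", delays, tr, "delay_fs", "delta_pdf_integral", header
            )
        write_curve_csv(
            outdir / "c3c10_s1.csv",
            ens.time_grid,
            report.c3c10_s1_trace,
            "t_fs",
            "r_C3C10_A",
            header,
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        logger.info("artifacts written to %s", outdir)
    return report
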