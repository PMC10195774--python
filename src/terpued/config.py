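"""Pipeline configuration: serializable, hashable, round-trippable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .diffraction import TransformConfig
from .kinetics import DEFAULT_REGIONS, RegionDefinition
from .surrogate import SurrogateParams

__all__ = ["PipelineConfig", "config_hash", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one analysis run.

    ``manifest`` points at a saved ensemble; when it is None the surrogate
    generator supplies the data.  ``delta_dt`` is the delay spacing at which
    ΔPDFs are evaluated (the native ensemble grid is finer).
    """

    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    manifest: str | None = None
    transform: TransformConfig = field(default_factory=TransformConfig)
    regions: tuple[RegionDefinition, ...] = DEFAULT_REGIONS
    irf_fwhm: float = 150.0
    excitation_fraction: float = 0.0156
    delta_dt: float = 50.0
    fit_window_fs: float = 400.0
    n_resamples: int = 200
    open_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.irf_fwhm <= 0:
            raise ValueError("irf_fwhm must be positive")
        if not 0 < self.excitation_fraction <= 1:
            raise ValueError("excitation_fraction must be in (0, 1]")
        if self.delta_dt <= 0:
            raise ValueError("delta_dt must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [asdict(r) for r in self.regions]
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        if "surrogate" in data and isinstance(data["surrogate"], Mapping):
            data["surrogate"] = SurrogateParams(**data["surrogate"])
        if "transform" in data and isinstance(data["transform"], Mapping):
            data["transform"] = TransformConfig(**data["transform"])
        if "regions" in data:
            data["regions"] = tuple(
                RegionDefinition(**r) if isinstance(r, Mapping) else r
                for r in data["regions"]
            )
        return cls(**data)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))
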