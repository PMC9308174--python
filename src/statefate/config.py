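"""Run configuration: a single YAML file validated before any computation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .scenarios import ModelParams


class ConfigError(ValueError):
    pass


_GEOMETRIES = ("continuum", "graph", "both")


@dataclass
class RunConfig:
    """Validated configuration for the command-line pipelines."""

    seed: int = 0
    geometry: str = "both"
    n_cells: int = 3000
    n_genes: int = 200
    T: float = 100.0
    dt: float | None = None
    fraction: float = 0.1
    nu: float = 0.005
    kappa: float = 100.0
    dbar: float = 1.0
    kde_bandwidth: float = 0.05
    grid_shape: tuple[int, int] = (100, 100)
    points_per_unit: float = 100.0
    knn_k: int = 15
    paga_threshold: float = 0.01
    scheme: str = "exponential"
    snapshot_times: list[float] = field(default_factory=list)
    rates: dict[str, tuple[float, float]] | None = None
    perturbation: dict[str, float] = field(default_factory=dict)
    extreme: bool = False

    def __post_init__(self) -> None:
        errors = []
        if self.geometry not in _GEOMETRIES:
            errors.append(f"geometry: {self.geometry!r} not in {_GEOMETRIES}")
        if self.scheme not in ("exponential", "upwind"):
            errors.append(f"scheme: unknown scheme {self.scheme!r}")
        if not 0.0 < self.fraction <= 1.0:
            errors.append("fraction: must lie in (0, 1]")
        if self.nu <= 0:
            errors.append("nu: must be positive")
        if self.kappa < 0:
            errors.append("kappa: must be non-negative")
        if self.dbar <= 0:
            errors.append("dbar: must be positive")
        if self.kde_bandwidth <= 0:
            errors.append("kde_bandwidth: must be positive")
        if self.T <= 0:
            errors.append("T: must be positive")
        if self.dt is not None and self.dt <= 0:
            errors.append("dt: must be positive when given")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 8:
            errors.append("grid_shape: two axes of at least 8 points")
        if errors:
            raise ConfigError("; ".join(errors))
        self.grid_shape = tuple(int(m) for m in self.grid_shape)

    def model_params(self) -> ModelParams:
        return ModelParams(
            nu=self.nu, kappa=self.kappa, dbar=self.dbar,
            kde_bandwidth=self.kde_bandwidth, grid_shape=self.grid_shape,
            points_per_unit=self.points_per_unit, knn_k=self.knn_k,
            paga_threshold=self.paga_threshold, fraction=self.fraction,
            rates=self.rates, scheme=self.scheme)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
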