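"""Run configuration: every model parameter in one flat, serializable record.

Defaults follow the published operating point of the model: time step
dt = 0.1, length weight v = 0.2, regularization weight mu = 1.0, VVF weight
lam_vvf = -0.1 (negative: extend along vessels), vesselness gate tau = 0.05,
speed threshold eps_v = 0.05, initialization height rho = 2, evaluation
window radius 12, and the kernel scale derived from the image size unless
overridden. The remaining fields (band width, freeze patience, stopping
rule) are implementation parameters documented in docs/methods.md.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # localization kernel / regularized step functions
    sigma: float | None = None  # None: round((H + W) / 16)
    eps_h: float = 1.0
    # energy weights
    lambda1: float = 1.0
    lambda2: float = 1.0
    v: float = 0.2
    mu: float = 1.0
    # evolution
    dt: float = 0.1
    lam_vvf: float = -0.1
    max_iters: int = 300
    band_width: int = 4
    freeze_patience: int | None = 10  # None disables freezing
    steady_tol: float = 1e-4  # per-iteration |delta phi| below this counts as "not moving"
    stop_frac: float = 1e-3
    stop_patience: int = 20
    # vesselness / VVF
    alpha: float = 0.5
    beta: float | None = None  # None: per-scale adaptive (half of max S)
    scales: list = field(default_factory=lambda: [1.0, 1.5, 2.0, 3.0])
    tau: float = 0.05
    eps_v: float = 0.05
    dark_vessels: bool = False  # invert the image for dark-on-bright vessels
    # initialization
    rho: float = 2.0
    init_threshold: float = 0.05
    min_object_px: int = 20
    # evaluation
    mrmse_radius: float = 12.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.band_width < 2:
            raise ValueError("band_width must be >= 2")
        if self.freeze_patience is not None and self.freeze_patience < 1:
            raise ValueError("freeze_patience must be >= 1 (or None)")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - cls.field_names()
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
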