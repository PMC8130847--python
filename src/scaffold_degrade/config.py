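"""YAML run configuration, validated with pydantic.

Layout::

    kinetics: {a, b, c, m, n, epsilon0}     # degradation-law constants
    artery:   {C10, C20, C30, C40, C50, C60}  # hyperelastic wall, MPa
    run:      {dt, horizon, snapshot_interval, mode}  # stepping, days

Every block and field is optional; omitted values fall back to the
published-fit defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .artery import ArteryCoefficients
from .kinetics import DegradationCoefficients
from .simulator import SimulationConfig

__all__ = ["KineticsBlock", "ArteryBlock", "RunBlock", "AppConfig", "load_config"]


class KineticsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: float = 0.385
    b: float = 0.152
    c: float = 0.616
    m: float = 0.342
    n: float = 0.236
    epsilon0: float = 1.22

    def to_coefficients(self) -> DegradationCoefficients:
        return DegradationCoefficients(**self.model_dump())


class ArteryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    C10: float = 6.52e-3
    C20: float = 4.89e-2
    C30: float = 9.26e-3
    C40: float = 0.76
    C50: float = -0.43
    C60: float = 8.69e-2

    def to_coefficients(self) -> ArteryCoefficients:
        return ArteryCoefficients(**self.model_dump())


class RunBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt: float = 0.5
    horizon: float = 180.0
    snapshot_interval: float = 30.0
    mode: str = "equivalent_time"


class AppConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kinetics: KineticsBlock = KineticsBlock()
    artery: ArteryBlock = ArteryBlock()
    run: RunBlock = RunBlock()

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            dt=self.run.dt,
            horizon=self.run.horizon,
            snapshot_interval=self.run.snapshot_interval,
            coefficients=self.kinetics.to_coefficients(),
            mode=self.run.mode,
        )


def load_config(path: str | Path | None) -> AppConfig:
    """Load a YAML config; ``None`` yields all defaults."""
    if path is None:
        return AppConfig()
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return AppConfig.model_validate(data)
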