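"""Configuration objects shared across pipeline stages.

All physical geometry is parameterized in micrometres and converted to
pixels through ``pixel_size_um``; time in hours through ``frame_interval_h``.
Defaults follow the published analysis parameters where one exists
(10 um zones/bins, 1.5 um cytoplasmic band, 50/100 um rolling-ball radii,
green threshold 0.225, quiescence ratio threshold 0.55, 24 h stall rule).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

DEFAULT_PIXEL_SIZE_UM = 0.65
DEFAULT_FRAME_INTERVAL_H = 0.5
DEFAULT_Z_STEP_UM = 10.0

ZONE_WIDTH_UM = 10.0
BAND_WIDTH_UM = 1.5
CDK2_ROLLBALL_UM = 50.0
SPHEROID_ROLLBALL_UM = 100.0
GREEN_FRACTION_THRESHOLD = 0.225
QUIESCENCE_RATIO_THRESHOLD = 0.55
NONCYCLING_HOURS = 24.0


@dataclass(frozen=True)
class SimulationConfig:
    """Physical calibration and seeding for every synthetic generator.

    A fixed ``seed`` makes each generator bitwise reproducible.
    """

    seed: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_h: float = DEFAULT_FRAME_INTERVAL_H

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_interval_h <= 0:
            raise ValueError(
                f"frame_interval_h must be > 0, got {self.frame_interval_h}"
            )

    def rng(self, salt: int = 0):
        """Derive a module-local generator from the config seed.

        ``salt`` separates independent random streams drawn from one config.
        """
        import numpy as np

        return np.random.default_rng((self.seed, salt))


@dataclass
class RunConfig:
    """Effective parameter set for a pipeline run; serializable to YAML."""

    seed: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_h: float = DEFAULT_FRAME_INTERVAL_H
    z_step_um: float = DEFAULT_Z_STEP_UM
    zone_width_um: float = ZONE_WIDTH_UM
    band_width_um: float = BAND_WIDTH_UM
    cdk2_rollball_um: float = CDK2_ROLLBALL_UM
    spheroid_rollball_um: float = SPHEROID_ROLLBALL_UM
    green_threshold: float = GREEN_FRACTION_THRESHOLD
    quiescence_threshold: float = QUIESCENCE_RATIO_THRESHOLD
    noncycling_hours: float = NONCYCLING_HOURS
    stages: list[str] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**dict(data))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            pixel_size_um=self.pixel_size_um,
            frame_interval_h=self.frame_interval_h,
        )
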