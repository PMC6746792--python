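"""Pipeline configuration: validated, hashable, loadable from YAML or JSON.

All physical quantities are SI internally; field names carry the unit where
it is not SI (flow rates in µl/min, QC distances in µm, matching how the
instrument and the imaging software report them).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .hydro_calibration import (
    ChannelGeometry,
    FluidProperties,
    HydroContext,
    ParticleProperties,
)
from .traction import InterfaceModel

#: cell heights observed on these cells span 3-8 µm; reference heights outside
#: this band are accepted with a warning
CELL_HEIGHT_BAND = (3e-6, 8e-6)


class QCThresholds(BaseModel):
    model_config = ConfigDict(frozen=True)

    min_track_samples: int = 5
    min_r_squared: float = 0.8
    wall_min_distance_um: float = 200.0

    @model_validator(mode="after")
    def _check(self) -> "QCThresholds":
        if self.min_track_samples < 2:
            raise ValueError("min_track_samples must be >= 2")
        if not (0.0 <= self.min_r_squared <= 1.0):
            raise ValueError("min_r_squared must lie in [0, 1]")
        if self.wall_min_distance_um < 0:
            raise ValueError("wall_min_distance_um must be >= 0")
        return self


class PipelineConfig(BaseModel):
    """Top-level configuration shared by every subcommand."""

    model_config = ConfigDict(frozen=True)

    geometry: ChannelGeometry = ChannelGeometry()
    fluid: FluidProperties = FluidProperties()
    particle: ParticleProperties = ParticleProperties()
    interface: InterfaceModel = InterfaceModel()
    qc: QCThresholds = QCThresholds()
    reference_height: float = 5.0e-6  # m
    poisson_ratio: float = 0.4
    pixel_size: float = 1.0  # µm/px of the track CSVs
    frame_interval: float = 1.0  # s, overridden per subcommand where needed
    flow_axis: tuple[float, float] = (1.0, 0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.reference_height <= 0:
            raise ValueError("reference_height must be > 0")
        lo, hi = CELL_HEIGHT_BAND
        if not (lo <= self.reference_height <= hi):
            warnings.warn(
                f"reference height {self.reference_height:.2g} m outside the "
                f"typical cell-height band [{lo:.0e}, {hi:.0e}] m",
                stacklevel=2,
            )
        return self

    @property
    def hydro_context(self) -> HydroContext:
        return HydroContext(
            geometry=self.geometry,
            fluid=self.fluid,
            particle=self.particle,
            reference_height=self.reference_height,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or JSON config file; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)
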