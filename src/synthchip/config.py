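"""Structured configuration for full-platform runs.

One YAML (or JSON) file gathers every tunable of the simulator —
decoder geometry, RC constants, fluids, SDA geometry, synthesis-cycle
timing — plus the single master seed from which all per-module random
streams are split.  Unknown keys are rejected so that a typo cannot
silently fall back to a default, and a round-trip through the file
format reproduces the configuration exactly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .addressing import ArrayGeometry
from .dynamics import RCParams
from .flow.fluids import FluidPair
from .flow.geometry import SDAGeometry

__all__ = ["Config", "load_config", "save_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometrySection(_Section):
    n_rows: int = 3163
    n_cols: int = 3163
    n_blocks: int = 128
    pitch_um: float = 3.16

    def build(self) -> ArrayGeometry:
        return ArrayGeometry(
            n_rows=self.n_rows, n_cols=self.n_cols,
            n_blocks=self.n_blocks, pitch_um=self.pitch_um,
        )


class RCSection(_Section):
    C_farad: float = 1e-12
    V_dd: float = 5.0
    R_on_ohm: float | None = None   # None -> calibrated from (80 ns, 3 V)
    R_off_ohm: float = 2.5e11

    def build(self) -> RCParams:
        return RCParams(C=self.C_farad, V_dd=self.V_dd,
                        R_on=self.R_on_ohm, R_off=self.R_off_ohm)


class FluidSection(_Section):
    mu_c: float = 1.365e-3
    rho_c: float = 1.82e3
    mu_d: float = 1.0e-3
    rho_d: float = 1.0e3
    sigma: float = 0.040
    theta_wall_deg: float = 135.0

    def build(self) -> FluidPair:
        return FluidPair(**self.model_dump())


class SDASection(_Section):
    unit_pitch: float = 3.16
    valve_width: float = 0.2
    chamber_width: float = 1.78
    chamber_height: float = 1.3
    neck_width: float = 0.3
    channel_width: float = 0.6
    mouth_width: float = 0.4
    bypass_width: float = 0.4
    wall_thickness: float = 0.2
    n_units_x: int = 4
    n_units_y: int = 4
    mirrored: bool = True
    cells_per_pitch: int = 32

    def build(self) -> SDAGeometry:
        return SDAGeometry(**self.model_dump())


class SynthesisSection(_Section):
    t_charge_ns: float = 80.0
    t_hold_s: float = 60.0


class Config(_Section):
    """Top-level configuration (see module docstring)."""

    geometry: GeometrySection = Field(default_factory=GeometrySection)
    rc: RCSection = Field(default_factory=RCSection)
    fluid: FluidSection = Field(default_factory=FluidSection)
    sda: SDASection = Field(default_factory=SDASection)
    synthesis: SynthesisSection = Field(default_factory=SynthesisSection)
    seed: int = 0

    def to_dict(self) -> dict:
        return self.model_dump()


def load_config(path) -> Config:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return Config.model_validate(data)


def save_config(path, config: Config) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
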