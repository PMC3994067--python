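"""Run configuration: site, parameter blocks, and model switches.

Defaults reproduce the maize-field parameter set used throughout the
package (fitted stomatal and soil-resistance coefficients, standard
optical and aerodynamic constants).  A YAML file can override any
subset; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .resistances import AeroParams, SoilResistanceParams
from .solar import SiteGeometry
from .stomatal import StomatalParams


@dataclass(frozen=True)
class OpticalConfig:
    """Leaf/canopy optical constants for PAR."""

    leaf_absorptivity: float = 0.8
    g_l: float = 0.5
    kappa_d: float = 0.7
    tau_a: float = 0.72
    f_a: float = 0.43


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulation needs besides the forcing table."""

    site: SiteGeometry = field(
        default_factory=lambda: SiteGeometry(latitude=37.87, longitude=102.85, altitude=1581.0)
    )
    stomatal: StomatalParams = field(default_factory=StomatalParams)
    soil_resistance: SoilResistanceParams = field(default_factory=SoilResistanceParams)
    aero: AeroParams = field(default_factory=AeroParams)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    theta_field: float = 0.30
    theta_wilt: float = 0.12
    theta_sat: float = 0.42
    conductance_model: str = "dualleaf"
    bigleaf_mean_irradiance: str = "per_lai"
    inversion_mode: str = "coupled"   # or "measured_vpd"
    wind_height: float = 2.0

    def __post_init__(self) -> None:
        if self.conductance_model not in ("bigleaf", "dualleaf"):
            raise ValueError("conductance_model must be 'bigleaf' or 'dualleaf'")
        if self.inversion_mode not in ("coupled", "measured_vpd"):
            raise ValueError("inversion_mode must be 'coupled' or 'measured_vpd'")


_BLOCKS = {
    "site": SiteGeometry,
    "stomatal": StomatalParams,
    "soil_resistance": SoilResistanceParams,
    "aero": AeroParams,
    "optics": OpticalConfig,
}


def _build_block(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__} block: {sorted(unknown)}")
    return cls(**data)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The file may contain any subset of the nested blocks (``site``,
    ``stomatal``, ``soil_resistance``, ``aero``, ``optics``) and the
    top-level scalars; everything omitted keeps its default.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            kwargs[key] = value if not isinstance(value, dict) else _build_block(_BLOCKS[key], value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
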