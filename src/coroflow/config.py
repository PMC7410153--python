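"""Strict YAML/JSON configuration schemas and loaders.

Every config surface is schema-validated with unknown keys rejected, so a
typo in a bench config fails loudly instead of silently falling back to a
default.  Loaders accept ``.yaml``/``.yml``/``.json`` files and return the
package's domain objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .catheter import CatalogEntry, CatheterCatalog, DEFAULT_MAX_LENGTH_CM
from .network import BranchModel, PhantomNetwork
from .presets import Activity, ActivityPresets, Vessel
from .units import FluidProperties, mmhg_to_dynes_cm2

__all__ = [
    "FluidConfig",
    "CatalogConfig",
    "PresetsConfig",
    "NetworkConfig",
    "load_config_file",
    "load_fluid",
    "load_catalog",
    "load_presets",
    "load_network",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FluidConfig(_StrictModel):
    viscosity_poise: float = Field(0.037, gt=0)
    density: float = Field(1.0, gt=0)

    def build(self) -> FluidProperties:
        return FluidProperties(self.viscosity_poise, self.density)


class CatalogEntryConfig(_StrictModel):
    fr: int = Field(gt=0)
    inner_radius_cm: float = Field(gt=0)
    min_length_cm: float = Field(0.0, ge=0)
    max_length_cm: float = Field(DEFAULT_MAX_LENGTH_CM, gt=0)


class CatalogConfig(_StrictModel):
    catalog: list[CatalogEntryConfig]

    def build(self) -> CatheterCatalog:
        return CatheterCatalog(
            tuple(
                CatalogEntry(e.fr, e.inner_radius_cm, e.min_length_cm, e.max_length_cm)
                for e in self.catalog
            )
        )


class PresetsConfig(_StrictModel):
    """Map vessel → {activity: resistance dynes·s/cm⁵}."""

    presets: dict[str, dict[str, float]]

    def build(self) -> ActivityPresets:
        table: dict[tuple[Vessel, Activity], float] = {}
        for vessel_key, by_activity in self.presets.items():
            vessel = Vessel(vessel_key)
            for activity_key, value in by_activity.items():
                table[(vessel, Activity(activity_key))] = value
        return ActivityPresets(table)


class BranchConfig(_StrictModel):
    vessel: str
    chamber_resistance: float = Field(ge=0)
    catheter_resistance: float = Field(0.0, ge=0)
    artery_resistance: float = Field(0.0, ge=0)
    chamber_compliance: float | None = Field(None, gt=0)
    outlet_pressure_mmHg: float = 0.0


class InletConfig(_StrictModel):
    pressure_mmHg: float | None = None
    flow_cm3_s: float | None = None


class NetworkConfig(_StrictModel):
    inlet: InletConfig
    branches: list[BranchConfig]
    aortic_outlet_resistance: float | None = Field(None, gt=0)
    fluid: FluidConfig = FluidConfig()

    @field_validator("branches")
    @classmethod
    def _non_empty(cls, v: list[BranchConfig]) -> list[BranchConfig]:
        if not v:
            raise ValueError("network needs at least one branch")
        return v

    def build(self) -> PhantomNetwork:
        return PhantomNetwork(
            branches=tuple(
                BranchModel(
                    vessel=b.vessel,
                    chamber_resistance=b.chamber_resistance,
                    catheter_resistance=b.catheter_resistance,
                    artery_resistance=b.artery_resistance,
                    chamber_compliance=b.chamber_compliance,
                    outlet_pressure=mmhg_to_dynes_cm2(b.outlet_pressure_mmHg),
                )
                for b in self.branches
            ),
            inlet_pressure=(
                mmhg_to_dynes_cm2(self.inlet.pressure_mmHg)
                if self.inlet.pressure_mmHg is not None
                else None
            ),
            inlet_flow=self.inlet.flow_cm3_s,
            aortic_outlet_resistance=self.aortic_outlet_resistance,
        )


def load_config_file(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_fluid(path: str | Path) -> FluidProperties:
    data = load_config_file(path)
    return FluidConfig.model_validate(data.get("fluid", data)).build()


def load_catalog(path: str | Path) -> CatheterCatalog:
    return CatalogConfig.model_validate(load_config_file(path)).build()


def load_presets(path: str | Path) -> ActivityPresets:
    return PresetsConfig.model_validate(load_config_file(path)).build()


def load_network(path: str | Path) -> PhantomNetwork:
    return NetworkConfig.model_validate(load_config_file(path)).build()
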