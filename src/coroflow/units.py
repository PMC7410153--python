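"""Unit system and physical constants.

All internal computation is in CGS units — centimetre, gram, second — because
hydraulic resistances in the coronary literature are quoted in dynes·s/cm⁵.
Public constructors accept the clinical units used on the bench (mmHg for
pressure, mL/min for flow) and convert on entry.

Conversions are exact linear maps:

* 1 mmHg = 1333.22 dyn/cm² (standard value; fixed, not configurable)
* 1 Pa   = 10 dyn/cm² (SI/CGS definition)
* 1 mL/min = 1/60 cm³/s (exact rational)
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DYNES_PER_CM2_PER_MMHG",
    "DYNES_PER_CM2_PER_PA",
    "FluidProperties",
    "Pressure",
    "FlowRate",
    "HydraulicResistance",
    "Compliance",
    "UnknownUnitError",
    "convert_flow",
    "convert_pressure",
    "mmhg_to_dynes_cm2",
    "dynes_cm2_to_mmhg",
    "ml_min_to_cm3_s",
    "cm3_s_to_ml_min",
]

#: dyn/cm² per mmHg — fixed conversion constant.
DYNES_PER_CM2_PER_MMHG = 1333.22

#: dyn/cm² per pascal — CGS/SI definition.
DYNES_PER_CM2_PER_PA = 10.0


class UnknownUnitError(ValueError):
    """Raised when a unit string is not recognised."""

    def __init__(self, unit: str, known: tuple[str, ...]):
        self.unit = unit
        super().__init__(f"unknown unit {unit!r}; expected one of {', '.join(known)}")


def _normalise(unit: str) -> str:
    return unit.strip().lower().replace("^", "").replace("³", "3").replace("²", "2")


# canonical flow unit: cm³/s.  Factors convert *to* canonical.
_FLOW_FACTORS = {
    "cm3/s": 1.0,
    "cm3/sec": 1.0,
    "ml/s": 1.0,
    "ml/min": 1.0 / 60.0,
    "ml_min": 1.0 / 60.0,
    "l/min": 1000.0 / 60.0,
}

# canonical pressure unit: dyn/cm².
_PRESSURE_FACTORS = {
    "dyn/cm2": 1.0,
    "dynes/cm2": 1.0,
    "dynes_cm2": 1.0,
    "ba": 1.0,
    "mmhg": DYNES_PER_CM2_PER_MMHG,
    "pa": DYNES_PER_CM2_PER_PA,
    "kpa": 1000.0 * DYNES_PER_CM2_PER_PA,
}


def _factor(unit: str, table: dict[str, float], kind: str) -> float:
    try:
        return table[_normalise(unit)]
    except KeyError:
        raise UnknownUnitError(unit, tuple(sorted(table))) from None


def convert_flow(q: float, from_unit: str, to_unit: str) -> float:
    """Convert a volumetric flow rate between mL/min, cm³/s and L/min."""
    return q * _factor(from_unit, _FLOW_FACTORS, "flow") / _factor(to_unit, _FLOW_FACTORS, "flow")


def convert_pressure(p: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg, dyn/cm² and Pa."""
    return p * _factor(from_unit, _PRESSURE_FACTORS, "pressure") / _factor(
        to_unit, _PRESSURE_FACTORS, "pressure"
    )


def mmhg_to_dynes_cm2(p_mmhg: float) -> float:
    return p_mmhg * DYNES_PER_CM2_PER_MMHG


def dynes_cm2_to_mmhg(p_dyn: float) -> float:
    return p_dyn / DYNES_PER_CM2_PER_MMHG


def ml_min_to_cm3_s(q_ml_min: float) -> float:
    return q_ml_min / 60.0


def cm3_s_to_ml_min(q_cm3_s: float) -> float:
    return q_cm3_s * 60.0


@dataclass(frozen=True)
class FluidProperties:
    """Working fluid of the flow loop.

    Parameters
    ----------
    dynamic_viscosity : float
        Dynamic viscosity μ in poise (g·cm⁻¹·s⁻¹).  The default 0.037 P
        (3.7 cP) is a blood-analog viscosity; whole blood at 37 °C is
        typically 3–4 cP.  Every sizing routine accepts an override.
    density : float
        Fluid density in g/cm³; only relevant to inertial extensions, kept
        for completeness.  Defaults to 1.0 (water-like).
    """

    dynamic_viscosity: float = 0.037
    density: float = 1.0

    def __post_init__(self) -> None:
        if not self.dynamic_viscosity > 0:
            raise ValueError(f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}")
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")


@dataclass(frozen=True)
class Pressure:
    """A pressure stored canonically in dyn/cm²."""

    value: float  # dyn/cm²

    @classmethod
    def from_mmhg(cls, p_mmhg: float) -> "Pressure":
        return cls(mmhg_to_dynes_cm2(p_mmhg))

    @property
    def mmhg(self) -> float:
        return dynes_cm2_to_mmhg(self.value)


@dataclass(frozen=True)
class FlowRate:
    """A volumetric flow rate stored canonically in cm³/s."""

    value: float  # cm³/s

    @classmethod
    def from_ml_min(cls, q_ml_min: float) -> "FlowRate":
        return cls(ml_min_to_cm3_s(q_ml_min))

    @property
    def ml_min(self) -> float:
        return cm3_s_to_ml_min(self.value)


@dataclass(frozen=True)
class HydraulicResistance:
    """Hydraulic resistance ΔP/Q in dynes·s/cm⁵."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"resistance must be >= 0, got {self.value}")


@dataclass(frozen=True)
class Compliance:
    """Volume compliance dV/dP in cm⁵/dyne."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"compliance must be > 0, got {self.value}")
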