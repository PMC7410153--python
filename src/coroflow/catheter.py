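"""Poiseuille-law sizing of distal-resistance catheters.

A catheter of inner radius ``r`` and length ``L`` carrying fully developed
laminar flow of a fluid with dynamic viscosity ``μ`` presents the hydraulic
resistance

    R = 8 μ L / (π r⁴)        [dynes·s/cm⁵, CGS]

Spliced downstream of a phantom's outflow chamber, such a catheter imposes a
chosen capillary-bed resistance on one coronary branch.  This module solves
the forward problem (resistance from geometry), the inverse problem (length
from a target resistance), applies the chamber-resistance correction, and
selects catheters from a catalog of commercially available French sizes.

Entrance/exit losses and turbulence corrections are deliberately ignored:
at bench flow rates (1–3 cm³/s) in sub-millimetre lumens the flow is
strongly laminar and the fully developed term dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.optimize import minimize_scalar

from .presets import (
    CORONARY_RESISTANCE,
    REFERENCE_CATHETER_LENGTHS_CM,
    Activity,
    ActivityPresets,
    Vessel,
)
from .units import FluidProperties

__all__ = [
    "CatheterSpec",
    "CatalogEntry",
    "CatheterCatalog",
    "ResistanceTarget",
    "DesignOption",
    "DesignResult",
    "poiseuille_resistance",
    "poiseuille_length",
    "required_distal_resistance",
    "design_for_target",
    "build_quantized_set",
    "quantization_error",
    "fit_viscosity",
]

#: inner lumen radii (cm) of the stock 4/5/6 French resistance catheters
DEFAULT_CATALOG_RADII_CM = {4: 0.06, 5: 0.071, 6: 0.09}

#: longest catheter routinely available from vendors (cm); lengths beyond it
#: require dropping to a smaller French size
DEFAULT_MAX_LENGTH_CM = 112.0

#: quantized-set defaults: multiples of 10,000 dynes·s/cm⁵ from 50k to 300k
DEFAULT_QUANTIZATION_STEP = 10_000.0
DEFAULT_SET_RANGE = (50_000.0, 300_000.0)


def poiseuille_resistance(
    radius_cm: float, length_cm: float, fluid: FluidProperties | None = None
) -> float:
    """Hydraulic resistance R = 8μL/(πr⁴) of a cylindrical catheter.

    Parameters are in CGS: radius and length in cm, viscosity in poise.
    Returns dynes·s/cm⁵.  A zero-length catheter has zero resistance.
    """
    fluid = fluid or FluidProperties()
    if not radius_cm > 0:
        raise ValueError(f"radius must be > 0 cm, got {radius_cm}")
    if length_cm < 0:
        raise ValueError(f"length must be >= 0 cm, got {length_cm}")
    return 8.0 * fluid.dynamic_viscosity * length_cm / (math.pi * radius_cm**4)


def poiseuille_length(
    target_resistance: float, radius_cm: float, fluid: FluidProperties | None = None
) -> float:
    """Catheter length realizing a target resistance: L = R·πr⁴/(8μ).

    Exact algebraic inverse of :func:`poiseuille_resistance`.
    """
    fluid = fluid or FluidProperties()
    if target_resistance < 0:
        raise ValueError(f"target resistance must be >= 0, got {target_resistance}")
    if not radius_cm > 0:
        raise ValueError(f"radius must be > 0 cm, got {radius_cm}")
    return target_resistance * math.pi * radius_cm**4 / (8.0 * fluid.dynamic_viscosity)


def required_distal_resistance(coronary: float, chamber: float) -> float:
    """Resistance the catheter must supply once the chamber's share is removed.

    The outflow chamber sits in series with the catheter, so its small
    intrinsic resistance is subtracted from the coronary target to avoid a
    systematic overshoot.
    """
    if chamber < 0:
        raise ValueError(f"chamber resistance must be >= 0, got {chamber}")
    if coronary <= chamber:
        raise ValueError(
            "non-physical configuration: chamber resistance "
            f"({chamber:g}) must be smaller than the coronary target ({coronary:g})"
        )
    return coronary - chamber


@dataclass(frozen=True)
class CatheterSpec:
    """A concrete catheter: French size, inner lumen radius and cut length."""

    french_size: int
    inner_radius_cm: float
    length_cm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.inner_radius_cm > 0:
            raise ValueError(f"inner_radius_cm must be > 0, got {self.inner_radius_cm}")
        if not self.length_cm > 0:
            raise ValueError(f"length_cm must be > 0, got {self.length_cm}")

    def resistance(self, fluid: FluidProperties | None = None) -> float:
        return poiseuille_resistance(self.inner_radius_cm, self.length_cm, fluid)


@dataclass(frozen=True)
class CatalogEntry:
    french_size: int
    inner_radius_cm: float
    min_length_cm: float = 0.0
    max_length_cm: float = DEFAULT_MAX_LENGTH_CM

    def __post_init__(self) -> None:
        if not self.inner_radius_cm > 0:
            raise ValueError(f"inner_radius_cm must be > 0, got {self.inner_radius_cm}")
        if not self.min_length_cm < self.max_length_cm:
            raise ValueError(
                f"min_length_cm ({self.min_length_cm}) must be < max_length_cm "
                f"({self.max_length_cm})"
            )


@dataclass(frozen=True)
class CatheterCatalog:
    """Available catheter stock: one entry per French size.

    Inner radii must increase strictly with French size.
    """

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("catalog must contain at least one entry")
        ordered = sorted(self.entries, key=lambda e: e.french_size)
        radii = [e.inner_radius_cm for e in ordered]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("inner radii must increase strictly with French size")
        object.__setattr__(self, "entries", tuple(ordered))

    @classmethod
    def default(cls) -> "CatheterCatalog":
        return cls(
            tuple(
                CatalogEntry(fr, r) for fr, r in sorted(DEFAULT_CATALOG_RADII_CM.items())
            )
        )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ResistanceTarget:
    """A distal resistance to realize, tagged by vessel and activity state."""

    resistance: float
    vessel: Vessel | None = None
    activity: Activity | None = None

    def __post_init__(self) -> None:
        if not self.resistance > 0:
            raise ValueError(f"target resistance must be > 0, got {self.resistance}")
        if self.vessel is not None:
            object.__setattr__(self, "vessel", Vessel(self.vessel))
        if self.activity is not None:
            object.__setattr__(self, "activity", Activity(self.activity))

    @classmethod
    def from_preset(
        cls, vessel: Vessel, activity: Activity, presets: ActivityPresets | None = None
    ) -> "ResistanceTarget":
        presets = presets or ActivityPresets.default()
        vessel, activity = Vessel(vessel), Activity(activity)
        return cls(presets[(vessel, activity)], vessel=vessel, activity=activity)


@dataclass(frozen=True)
class DesignOption:
    spec: CatheterSpec
    achieved_resistance: float
    relative_error: float
    feasible: bool
    infeasibility_reason: str | None = None


@dataclass(frozen=True)
class DesignResult:
    target: ResistanceTarget
    chamber_correction: float
    options: tuple[DesignOption, ...]

    @property
    def best(self) -> DesignOption:
        return self.options[0]

    @property
    def feasible_options(self) -> tuple[DesignOption, ...]:
        return tuple(o for o in self.options if o.feasible)


def design_for_target(
    target: ResistanceTarget | float,
    catalog: CatheterCatalog | None = None,
    fluid: FluidProperties | None = None,
    chamber_correction: float = 0.0,
) -> DesignResult:
    """Size one catheter per catalog radius for a distal resistance target.

    The chamber correction (the chamber's own series resistance) is
    subtracted from the target before inversion.  Each option's length is the
    exact Poiseuille inverse; options falling outside the catalog's length
    window are returned flagged infeasible with an actionable reason.
    Options are ordered feasible-first, then by |relative error|, then by
    French size (smaller sizes give shorter catheters and less dead volume).
    """
    if not isinstance(target, ResistanceTarget):
        target = ResistanceTarget(float(target))
    catalog = catalog or CatheterCatalog.default()
    fluid = fluid or FluidProperties()
    distal = required_distal_resistance(target.resistance, chamber_correction)

    options: list[DesignOption] = []
    for entry in catalog:
        length = poiseuille_length(distal, entry.inner_radius_cm, fluid)
        achieved = poiseuille_resistance(entry.inner_radius_cm, length, fluid)
        rel_err = (achieved - distal) / distal
        reason = None
        if length > entry.max_length_cm:
            reason = (
                f"length {length:.1f} cm exceeds max {entry.max_length_cm:g} cm — "
                "use smaller Fr"
            )
        elif length < entry.min_length_cm:
            reason = (
                f"length {length:.1f} cm below min {entry.min_length_cm:g} cm — "
                "use larger Fr"
            )
        label = f"{entry.french_size}Fr x {length:.1f}cm"
        options.append(
            DesignOption(
                spec=CatheterSpec(entry.french_size, entry.inner_radius_cm, length, label),
                achieved_resistance=achieved,
                relative_error=rel_err,
                feasible=reason is None,
                infeasibility_reason=reason,
            )
        )

    # round the error key so float noise cannot scramble the Fr tie-break
    options.sort(
        key=lambda o: (not o.feasible, round(abs(o.relative_error), 9), o.spec.french_size)
    )
    return DesignResult(target=target, chamber_correction=chamber_correction, options=tuple(options))


def build_quantized_set(
    r_min: float = DEFAULT_SET_RANGE[0],
    r_max: float = DEFAULT_SET_RANGE[1],
    step: float = DEFAULT_QUANTIZATION_STEP,
    catalog: CatheterCatalog | None = None,
    fluid: FluidProperties | None = None,
) -> list[DesignResult]:
    """Design a bench set of catheters at every multiple of ``step`` in range.

    A quantized set (default: 50,000–300,000 dynes·s/cm⁵ in 10,000 steps)
    lets the experimenter swap resistances quickly instead of cutting a
    bespoke catheter per condition.
    """
    if not 0 < r_min <= r_max:
        raise ValueError(f"require 0 < r_min <= r_max, got ({r_min}, {r_max})")
    if not step > 0:
        raise ValueError(f"step must be > 0, got {step}")
    first = math.ceil(r_min / step - 1e-9)
    last = math.floor(r_max / step + 1e-9)
    return [
        design_for_target(ResistanceTarget(k * step), catalog, fluid)
        for k in range(first, last + 1)
    ]


def quantization_error(true_target: float, step: float = DEFAULT_QUANTIZATION_STEP) -> float:
    """Relative error from snapping a target to the nearest step multiple.

    Ties (exactly halfway between multiples) round up.  Bounded above by
    step / (2·true_target).
    """
    if not true_target > 0:
        raise ValueError(f"true_target must be > 0, got {true_target}")
    if not step > 0:
        raise ValueError(f"step must be > 0, got {step}")
    nearest = math.floor(true_target / step + 0.5) * step
    return abs(nearest - true_target) / true_target


def _reference_cells() -> list[tuple[float, float, float]]:
    """(target resistance, radius cm, reference length cm) triples."""
    return [
        (CORONARY_RESISTANCE[(v, a)], r, length)
        for (v, a, r), length in REFERENCE_CATHETER_LENGTHS_CM.items()
    ]


def fit_viscosity(
    cells: Sequence[tuple[float, float, float]] | None = None,
    bounds: tuple[float, float] = (0.005, 0.10),
) -> float:
    """Recover the working-fluid viscosity implied by a sizing table.

    Minimizes the mean relative error between Poiseuille lengths
    L(μ) = R·πr⁴/(8μ) and the tabulated lengths over all cells, via a
    bounded 1-D scalar search.  With the shipped reference table this
    recovers μ ≈ 0.037 poise, confirming the table is Poiseuille-consistent
    and identifying the blood-analog fluid behind it.

    Parameters
    ----------
    cells : sequence of (target_resistance, radius_cm, length_cm)
        Defaults to the shipped reference table.
    bounds : (low, high) poise
        Search interval.
    """
    cells = list(cells) if cells is not None else _reference_cells()
    if not cells:
        raise ValueError("need at least one (resistance, radius, length) cell")

    def mean_rel_err(mu: float) -> float:
        fluid = FluidProperties(dynamic_viscosity=mu)
        return sum(
            abs(poiseuille_length(res, r, fluid) - length) / length
            for res, r, length in cells
        ) / len(cells)

    result = minimize_scalar(mean_rel_err, bounds=bounds, method="bounded",
                             options={"xatol": 1e-6})
    return float(result.x)
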