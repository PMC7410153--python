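"""Shipped defaults: vessels, activity states, and reference resistance data.

The three main coronary trees (LAD, LCX, RCA) each drain into their own
outflow chamber on the phantom, so every per-branch quantity in this package
is keyed by :class:`Vessel`.  Distal (capillary-bed) resistance falls as
physical activity rises — the vasculature dilates to raise coronary flow —
so sizing targets are additionally keyed by :class:`Activity`.

The numeric defaults are the values a phantom builder needs with no external
files: per-vessel distal resistances at rest, light exercise and moderate
exercise taken from lumped-parameter models of the human coronary
circulation, typical measured chamber resistances for the three-chamber
outflow base, and the reference catheter sizing table (radius → length) that
realizes those resistances with a 3.7 cP blood-analog fluid.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping


class Vessel(str, Enum):
    """The three main coronary arteries."""

    LAD = "LAD"
    LCX = "LCX"
    RCA = "RCA"


class Activity(str, Enum):
    """Physical-activity states the phantom can emulate."""

    REST = "rest"
    LIGHT_EXERCISE = "light_exercise"
    MODERATE_EXERCISE = "moderate_exercise"


#: ordering used for the monotonicity check (resistance falls with activity)
ACTIVITY_ORDER = (Activity.REST, Activity.LIGHT_EXERCISE, Activity.MODERATE_EXERCISE)

#: short column labels conventional for activity states in percent tables
ACTIVITY_LABELS = {
    Activity.REST: "R",
    Activity.LIGHT_EXERCISE: "E1",
    Activity.MODERATE_EXERCISE: "E2",
}

#: average distal coronary resistance (dynes·s/cm⁵) per vessel and activity,
#: from lumped-parameter models of the coronary circulation.
CORONARY_RESISTANCE: Mapping[tuple[Vessel, Activity], float] = {
    (Vessel.LAD, Activity.REST): 254_250.0,
    (Vessel.LCX, Activity.REST): 137_000.0,
    (Vessel.RCA, Activity.REST): 479_000.0,
    (Vessel.LAD, Activity.LIGHT_EXERCISE): 71_250.0,
    (Vessel.LCX, Activity.LIGHT_EXERCISE): 81_750.0,
    (Vessel.RCA, Activity.LIGHT_EXERCISE): 121_000.0,
    (Vessel.LAD, Activity.MODERATE_EXERCISE): 29_000.0,
    (Vessel.LCX, Activity.MODERATE_EXERCISE): 29_300.0,
    (Vessel.RCA, Activity.MODERATE_EXERCISE): 50_300.0,
}

#: typical measured intrinsic resistance (dynes·s/cm⁵) of the three-chamber
#: outflow base, per chamber, from constant-flow bench characterization.
MEASURED_CHAMBER_RESISTANCE: Mapping[Vessel, float] = {
    Vessel.LAD: 1671.0,
    Vessel.LCX: 1820.0,
    Vessel.RCA: 591.0,
}

#: reference catheter lengths (cm) that realize CORONARY_RESISTANCE with a
#: μ = 0.037 P fluid, keyed (vessel, activity, inner radius cm).  Used as the
#: validation benchmark for the Poiseuille sizing routines.
REFERENCE_CATHETER_LENGTHS_CM: Mapping[tuple[Vessel, Activity, float], float] = {
    (Vessel.LAD, Activity.REST, 0.06): 34.9,
    (Vessel.LAD, Activity.REST, 0.071): 68.5,
    (Vessel.LAD, Activity.REST, 0.09): 176.95,
    (Vessel.LCX, Activity.REST, 0.06): 18.8,
    (Vessel.LCX, Activity.REST, 0.071): 36.9,
    (Vessel.LCX, Activity.REST, 0.09): 95.3,
    (Vessel.RCA, Activity.REST, 0.06): 65.8,
    (Vessel.RCA, Activity.REST, 0.071): 129.1,
    (Vessel.RCA, Activity.REST, 0.09): 333.3,
    (Vessel.LAD, Activity.LIGHT_EXERCISE, 0.06): 9.7,
    (Vessel.LAD, Activity.LIGHT_EXERCISE, 0.071): 19.2,
    (Vessel.LAD, Activity.LIGHT_EXERCISE, 0.09): 49.5,
    (Vessel.LCX, Activity.LIGHT_EXERCISE, 0.06): 11.2,
    (Vessel.LCX, Activity.LIGHT_EXERCISE, 0.071): 22.0,
    (Vessel.LCX, Activity.LIGHT_EXERCISE, 0.09): 56.8,
    (Vessel.RCA, Activity.LIGHT_EXERCISE, 0.06): 16.6,
    (Vessel.RCA, Activity.LIGHT_EXERCISE, 0.071): 32.6,
    (Vessel.RCA, Activity.LIGHT_EXERCISE, 0.09): 84.2,
    (Vessel.LAD, Activity.MODERATE_EXERCISE, 0.06): 3.9,
    (Vessel.LAD, Activity.MODERATE_EXERCISE, 0.071): 7.8,
    (Vessel.LAD, Activity.MODERATE_EXERCISE, 0.09): 20.1,
    (Vessel.LCX, Activity.MODERATE_EXERCISE, 0.06): 4.0,
    (Vessel.LCX, Activity.MODERATE_EXERCISE, 0.071): 7.8,
    (Vessel.LCX, Activity.MODERATE_EXERCISE, 0.09): 20.3,
    (Vessel.RCA, Activity.MODERATE_EXERCISE, 0.06): 6.9,
    (Vessel.RCA, Activity.MODERATE_EXERCISE, 0.071): 13.5,
    (Vessel.RCA, Activity.MODERATE_EXERCISE, 0.09): 35.0,
}

#: reference cells flagged commercially unavailable (length beyond what
#: catheter vendors supply); all exceed the 112 cm catalog maximum.
UNAVAILABLE_REFERENCE_CELLS: frozenset[tuple[Vessel, Activity, float]] = frozenset(
    {
        (Vessel.LAD, Activity.REST, 0.09),
        (Vessel.RCA, Activity.REST, 0.071),
        (Vessel.RCA, Activity.REST, 0.09),
    }
)


@dataclass(frozen=True)
class ActivityPresets:
    """Complete map (vessel, activity) → distal resistance in dynes·s/cm⁵.

    Validates completeness (all 3 × 3 combinations) and the physiological
    ordering: per vessel, resistance is non-increasing from rest through
    light to moderate exercise.
    """

    resistances: Mapping[tuple[Vessel, Activity], float]

    def __post_init__(self) -> None:
        missing = [
            (v.value, a.value)
            for v in Vessel
            for a in Activity
            if (v, a) not in self.resistances
        ]
        if missing:
            raise ValueError(f"incomplete activity presets; missing {missing}")
        for v in Vessel:
            values = [self.resistances[(v, a)] for a in ACTIVITY_ORDER]
            if any(r <= 0 for r in values):
                raise ValueError(f"preset resistances must be > 0 for {v.value}")
            if not (values[0] >= values[1] >= values[2]):
                raise ValueError(
                    f"{v.value}: resistance must be non-increasing rest → light → moderate, "
                    f"got {values}"
                )

    @classmethod
    def default(cls) -> "ActivityPresets":
        return cls(dict(CORONARY_RESISTANCE))

    def __getitem__(self, key: tuple[Vessel, Activity]) -> float:
        vessel, activity = Vessel(key[0]), Activity(key[1])
        return self.resistances[(vessel, activity)]

    def for_activity(self, activity: Activity) -> dict[Vessel, float]:
        activity = Activity(activity)
        return {v: self.resistances[(v, activity)] for v in Vessel}
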