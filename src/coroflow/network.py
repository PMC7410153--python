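"""Lumped-parameter (0D) model of the phantom flow circuit.

The phantom is an aortic inlet feeding three parallel branches (LAD, LCX,
RCA).  Each branch is a series chain: the printed artery's own resistance
(usually negligible), the outflow chamber — a compliance ``C`` to ground plus
a small series resistance — and the distal-resistance catheter.  Electrically
this is one RC compartment per branch:

    C · dP_c/dt = Q_in − (P_c − P_out) / R_down,      R_down = R_chamber + R_catheter

with the chamber pressure ``P_c`` as the state.  At steady state each branch
obeys the hydraulic Ohm analog ΔP = Q·R_series, and the aortic node conserves
flow exactly.

Two drive modes are supported: a prescribed inlet pressure (pressure-driven)
or a prescribed total inlet flow (flow-driven, the programmable-pump mode).
The transient solver uses a fixed-step explicit Runge–Kutta (RK4) scheme with
a validated stability bound, and models the inlet ball valve (aortic-valve
surrogate) as an ideal check valve: reverse inlet flow is clipped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catheter import CatheterCatalog, ResistanceTarget, design_for_target
from .presets import Activity, ActivityPresets, Vessel
from .units import FluidProperties

__all__ = [
    "BranchModel",
    "PhantomNetwork",
    "SteadyStateSolution",
    "PulsatileSolution",
    "solve_steady_state",
    "simulate_transient",
    "apply_activity",
    "stability_dt_bound",
]

#: relative tolerance on nodal flow conservation
CONSERVATION_RTOL = 1e-9


@dataclass(frozen=True)
class BranchModel:
    """One coronary branch: artery → chamber (R, C) → catheter → outlet."""

    vessel: str
    chamber_resistance: float
    catheter_resistance: float
    artery_resistance: float = 0.0
    chamber_compliance: float | None = None
    outlet_pressure: float = 0.0  # dyn/cm², atmospheric reference

    def __post_init__(self) -> None:
        try:
            object.__setattr__(self, "vessel", Vessel(self.vessel).value)
        except ValueError:
            object.__setattr__(self, "vessel", str(self.vessel))
        for name in ("chamber_resistance", "catheter_resistance", "artery_resistance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.series_resistance <= 0:
            raise ValueError("total series resistance must be > 0")
        if self.chamber_compliance is not None and not self.chamber_compliance > 0:
            raise ValueError(
                f"chamber_compliance must be > 0 when set, got {self.chamber_compliance}"
            )

    @property
    def downstream_resistance(self) -> float:
        """Resistance distal of the compliance node (chamber + catheter)."""
        return self.chamber_resistance + self.catheter_resistance

    @property
    def series_resistance(self) -> float:
        return self.artery_resistance + self.downstream_resistance


@dataclass(frozen=True)
class PhantomNetwork:
    """Aortic inlet plus parallel branches; exactly one drive mode set."""

    branches: tuple[BranchModel, ...]
    inlet_pressure: float | None = None  # dyn/cm²
    inlet_flow: float | None = None  # cm³/s
    aortic_outlet_resistance: float | None = None

    def __post_init__(self) -> None:
        if not self.branches:
            raise ValueError("network needs at least one branch")
        object.__setattr__(self, "branches", tuple(self.branches))
        if (self.inlet_pressure is None) == (self.inlet_flow is None):
            raise ValueError(
                "set exactly one of inlet_pressure (pressure-driven) or "
                "inlet_flow (flow-driven)"
            )
        names = [b.vessel for b in self.branches]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate branch names: {names}")
        if self.aortic_outlet_resistance is not None and not self.aortic_outlet_resistance > 0:
            raise ValueError("aortic_outlet_resistance must be > 0 when set")

    @property
    def pressure_driven(self) -> bool:
        return self.inlet_pressure is not None


@dataclass(frozen=True)
class SteadyStateSolution:
    """Branch flows and node pressures of a solved circuit (CGS units)."""

    inlet_pressure: float
    inlet_flow: float
    branch_flows: Mapping[str, float]
    chamber_pressures: Mapping[str, float]
    aortic_outlet_flow: float = 0.0

    @property
    def total_branch_flow(self) -> float:
        return sum(self.branch_flows.values())

    def conservation_residual(self) -> float:
        """Relative flow-conservation error at the aortic node."""
        out = self.total_branch_flow + self.aortic_outlet_flow
        scale = max(abs(self.inlet_flow), abs(out), 1e-300)
        return abs(self.inlet_flow - out) / scale


def solve_steady_state(network: PhantomNetwork) -> SteadyStateSolution:
    """Solve the circuit at steady state (compliances carry no flow).

    Pressure-driven: each branch flow is (P_in − P_out)/R_series.
    Flow-driven: the aortic pressure is solved from nodal conservation,
    Q_in = Σ (P_a − P_out,b)/R_b (+ P_a/R_ao), then branch flows follow.
    """
    branches = network.branches
    conductances = np.array([1.0 / b.series_resistance for b in branches])
    outlets = np.array([b.outlet_pressure for b in branches])
    g_ao = (
        1.0 / network.aortic_outlet_resistance
        if network.aortic_outlet_resistance is not None
        else 0.0
    )

    if network.pressure_driven:
        p_in = float(network.inlet_pressure)
        flows = conductances * (p_in - outlets)
        q_ao = g_ao * p_in
        q_in = float(flows.sum() + q_ao)
    else:
        q_in = float(network.inlet_flow)
        # nodal equation: q_in = sum g_b (P - P_out,b) + g_ao * P
        p_in = (q_in + float(conductances @ outlets)) / (float(conductances.sum()) + g_ao)
        flows = conductances * (p_in - outlets)
        q_ao = g_ao * p_in

    chamber_p = {
        b.vessel: p_in - q * b.artery_resistance for b, q in zip(branches, flows)
    }
    return SteadyStateSolution(
        inlet_pressure=p_in,
        inlet_flow=q_in,
        branch_flows={b.vessel: float(q) for b, q in zip(branches, flows)},
        chamber_pressures=chamber_p,
        aortic_outlet_flow=float(q_ao),
    )


# ---------------------------------------------------------------------------
# transient (RC) simulation


def stability_dt_bound(network: PhantomNetwork, safety_factor: float = 10.0) -> float:
    """Largest admissible fixed step: 2·min(R_eff·C)/safety_factor.

    R_eff is the resistance the compliance actually sees — the downstream
    resistance in parallel with the upstream (artery) path when one exists.
    The factor-2 numerator is the explicit-Euler stability limit of a linear
    RC node; the safety factor keeps RK4 well inside it and accurate.
    """
    taus = []
    for b in network.branches:
        if b.chamber_compliance is None:
            raise ValueError(f"branch {b.vessel}: chamber_compliance required for transients")
        r_eff = b.downstream_resistance
        if b.artery_resistance > 0:
            r_eff = 1.0 / (1.0 / r_eff + 1.0 / b.artery_resistance)
        taus.append(b.chamber_compliance * r_eff)
    return 2.0 * min(taus) / safety_factor


@dataclass(frozen=True)
class PulsatileSolution:
    """Fixed-step time series of chamber pressures and branch flows."""

    times: np.ndarray
    inlet_flow: np.ndarray
    inlet_pressure: np.ndarray
    chamber_pressures: Mapping[str, np.ndarray]
    branch_inflows: Mapping[str, np.ndarray]
    branch_outflows: Mapping[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {
            "time_s": self.times,
            "inlet_flow_cm3_s": self.inlet_flow,
            "inlet_pressure_dyn_cm2": self.inlet_pressure,
        }
        for name, p in self.chamber_pressures.items():
            data[f"{name}_chamber_pressure_dyn_cm2"] = p
        for name, q in self.branch_outflows.items():
            data[f"{name}_outflow_cm3_s"] = q
        return pd.DataFrame(data)


def simulate_transient(
    network: PhantomNetwork,
    inflow_waveform: Callable[[float], float],
    duration: float,
    dt: float,
    initial_pressures: Mapping[str, float] | None = None,
    safety_factor: float = 10.0,
) -> PulsatileSolution:
    """Integrate the per-chamber RC dynamics under a prescribed inflow.

    The total pump inflow (clipped at zero by the ideal inlet check valve)
    enters the aortic node; branch inflows split through the artery
    resistances, each charging its chamber compliance, which discharges
    through the chamber + catheter resistance to the outlet:

        C_b · dP_b/dt = Q_in,b − (P_b − P_out,b) / R_down,b

    When every branch has zero artery resistance the network must be a single
    branch (the inflow is injected straight into its compartment); parallel
    branches need a finite artery resistance to define the flow split.

    Integrator: classic RK4 at a fixed step; ``dt`` must satisfy the
    stability bound of :func:`stability_dt_bound`.
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if not 0 < dt < duration:
        raise ValueError(f"dt must satisfy 0 < dt < duration, got {dt}")
    bound = stability_dt_bound(network, safety_factor)
    if dt > bound:
        raise ValueError(
            f"dt={dt:g} s exceeds the stability bound {bound:g} s "
            f"(2·min(RC)/{safety_factor:g}); reduce dt"
        )
    branches = network.branches
    direct = all(b.artery_resistance == 0 for b in branches)
    if direct and len(branches) > 1:
        raise ValueError(
            "multiple branches with zero artery resistance: the inflow split "
            "is undefined; set artery_resistance > 0 on each branch"
        )
    if not direct and any(b.artery_resistance == 0 for b in branches):
        raise ValueError("mixing zero and non-zero artery resistances is unsupported")

    c = np.array([b.chamber_compliance for b in branches], dtype=float)
    if np.any(np.isnan(c)):
        raise ValueError("all branches need chamber_compliance for transients")
    r_down = np.array([b.downstream_resistance for b in branches])
    p_out = np.array([b.outlet_pressure for b in branches])
    g_up = (
        None if direct else np.array([1.0 / b.artery_resistance for b in branches])
    )
    g_ao = (
        1.0 / network.aortic_outlet_resistance
        if network.aortic_outlet_resistance is not None
        else 0.0
    )

    def q_inlet(t: float) -> float:
        q = float(inflow_waveform(t))
        if not math.isfinite(q):
            raise ValueError(f"inflow waveform returned non-finite value at t={t:g}")
        return max(q, 0.0)  # ideal check valve at the inlet

    def split(t: float, p: np.ndarray) -> tuple[float, np.ndarray]:
        """Aortic pressure and per-branch inflows given chamber pressures."""
        q = q_inlet(t)
        if direct:
            return p[0], np.array([q])
        p_a = (q + float(g_up @ p)) / (float(g_up.sum()) + g_ao)
        return p_a, g_up * (p_a - p)

    def deriv(t: float, p: np.ndarray) -> np.ndarray:
        _, q_in = split(t, p)
        return (q_in - (p - p_out) / r_down) / c

    n_steps = int(round(duration / dt))
    times = dt * np.arange(n_steps + 1)
    p = np.array(
        [
            (initial_pressures or {}).get(b.vessel, 0.0)
            for b in branches
        ],
        dtype=float,
    )

    n_b = len(branches)
    p_hist = np.empty((n_steps + 1, n_b))
    pa_hist = np.empty(n_steps + 1)
    qin_hist = np.empty(n_steps + 1)
    qb_in_hist = np.empty((n_steps + 1, n_b))

    for i, t in enumerate(times):
        p_a, q_b = split(t, p)
        p_hist[i] = p
        pa_hist[i] = p_a
        qin_hist[i] = q_inlet(t)
        qb_in_hist[i] = q_b
        if i == n_steps:
            break
        k1 = deriv(t, p)
        k2 = deriv(t + dt / 2, p + dt / 2 * k1)
        k3 = deriv(t + dt / 2, p + dt / 2 * k2)
        k4 = deriv(t + dt, p + dt * k3)
        p = p + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    names = [b.vessel for b in branches]
    outflows = (p_hist - p_out) / r_down
    return PulsatileSolution(
        times=times,
        inlet_flow=qin_hist,
        inlet_pressure=pa_hist,
        chamber_pressures={n: p_hist[:, j].copy() for j, n in enumerate(names)},
        branch_inflows={n: qb_in_hist[:, j].copy() for j, n in enumerate(names)},
        branch_outflows={n: outflows[:, j].copy() for j, n in enumerate(names)},
    )


def apply_activity(
    network: PhantomNetwork,
    activity: Activity | str,
    presets: ActivityPresets | None = None,
    catalog: CatheterCatalog | None = None,
    fluid: FluidProperties | None = None,
) -> PhantomNetwork:
    """Return a new network with catheters re-sized for an activity state.

    Per branch, the catheter resistance is set to the preset distal
    resistance for (vessel, activity) minus the branch's own chamber
    resistance — the series-correction rule — realized through the catalog
    sizing routine.  The input network is not modified.
    """
    presets = presets or ActivityPresets.default()
    activity = Activity(activity)
    new_branches = []
    for b in network.branches:
        vessel = Vessel(b.vessel)
        target = ResistanceTarget.from_preset(vessel, activity, presets)
        result = design_for_target(
            target, catalog=catalog, fluid=fluid, chamber_correction=b.chamber_resistance
        )
        new_branches.append(replace(b, catheter_resistance=result.best.achieved_resistance))
    return replace(network, branches=tuple(new_branches))
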