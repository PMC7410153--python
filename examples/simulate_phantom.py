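"""Solve the three-branch phantom circuit at steady state and in time.

Builds the phantom network — aortic inlet at 100 mmHg, three parallel
branches each carrying its chamber resistance plus a catheter sized for the
rest state — solves the steady flows, re-sizes the catheters for moderate
exercise to show the flow increase, and finally integrates the RC transient
of one chamber charging from empty under constant inflow.
"""

import math

from coroflow import (
    BranchModel,
    MEASURED_CHAMBER_RESISTANCE,
    PhantomNetwork,
    Vessel,
    apply_activity,
    solve_steady_state,
    simulate_transient,
)
from coroflow.presets import Activity, ActivityPresets
from coroflow.units import mmhg_to_dynes_cm2, cm3_s_to_ml_min

presets = ActivityPresets.default()
branches = tuple(
    BranchModel(
        vessel=v.value,
        chamber_resistance=MEASURED_CHAMBER_RESISTANCE[v],
        catheter_resistance=presets[(v, Activity.REST)] - MEASURED_CHAMBER_RESISTANCE[v],
    )
    for v in Vessel
)
net = PhantomNetwork(branches=branches, inlet_pressure=mmhg_to_dynes_cm2(100.0))

for label, network in [("rest", net),
                       ("moderate exercise", apply_activity(net, "moderate_exercise"))]:
    sol = solve_steady_state(network)
    flows = "  ".join(f"{v}: {cm3_s_to_ml_min(q):6.1f} mL/min"
                      for v, q in sol.branch_flows.items())
    print(f"{label:18s} {flows}   (conservation residual "
          f"{sol.conservation_residual():.1e})")

# transient: LAD chamber charging from atmospheric under constant 80 mL/min
r_down = branches[0].downstream_resistance
compliance = 1e-4  # cm⁵/dyne, representative sealed-air chamber
tau = r_down * compliance
single = PhantomNetwork(
    branches=(BranchModel(vessel="LAD",
                          chamber_resistance=branches[0].chamber_resistance,
                          catheter_resistance=branches[0].catheter_resistance,
                          chamber_compliance=compliance),),
    inlet_flow=80.0 / 60.0,
)
sol = simulate_transient(single, lambda t: 80.0 / 60.0, duration=5 * tau, dt=tau / 100)
p = sol.chamber_pressures["LAD"]
print(f"\nRC charging, τ = R·C = {tau:.1f} s:")
for k in (1, 3, 5):
    i = int(k * tau / (sol.times[1] - sol.times[0]))
    frac = p[i] / p[-1] if k < 5 else 1.0
    print(f"  t = {k}τ: chamber pressure {p[i]:9.0f} dyn/cm² "
          f"({p[i] / mmhg_to_dynes_cm2(1):5.1f} mmHg), "
          f"{100 * (1 - math.exp(-k)):.1f}% of steady expected")
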