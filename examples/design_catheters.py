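"""Size distal-resistance catheters for each coronary branch and activity state.

Builds the default 4/5/6 Fr catalog and blood-analog fluid (3.7 cP), asks for
the catheter that realizes the rest-state LAD distal resistance after
subtracting the chamber's own series resistance, and prints the options.
The length column is the Poiseuille inverse L = R·πr⁴/(8μ); infeasible rows
are catheters longer than vendors supply (>112 cm).
"""

from coroflow import (
    CatheterCatalog,
    FluidProperties,
    MEASURED_CHAMBER_RESISTANCE,
    ResistanceTarget,
    Vessel,
    design_for_target,
    fit_viscosity,
)

fluid = FluidProperties()  # 0.037 poise
catalog = CatheterCatalog.default()

print(f"working fluid viscosity: {fluid.dynamic_viscosity} poise")
print(f"viscosity implied by the reference sizing table: {fit_viscosity():.4f} poise\n")

for vessel, activity in [(Vessel.LAD, "rest"), (Vessel.RCA, "rest"),
                         (Vessel.LAD, "moderate_exercise")]:
    target = ResistanceTarget.from_preset(vessel, activity)
    chamber = MEASURED_CHAMBER_RESISTANCE[vessel]
    result = design_for_target(target, catalog, fluid, chamber_correction=chamber)
    print(f"{vessel.value} {activity}: target {target.resistance:,.0f} dynes·s/cm⁵ "
          f"(− {chamber:,.0f} chamber)")
    for o in result.options:
        flag = "ok " if o.feasible else "NOT AVAILABLE"
        print(f"  {o.spec.french_size} Fr (r={o.spec.inner_radius_cm} cm): "
              f"{o.spec.length_cm:7.1f} cm  {flag}"
              f"{'  ' + o.infeasibility_reason if o.infeasibility_reason else ''}")
    print()
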