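"""Characterize the outflow chambers from a (synthetic) constant-flow sweep.

Generates the five-point 80–160 mL/min sweep for each chamber with 2%
relative pressure noise, estimates each chamber's resistance as the mean of
ΔP/Q (with the through-origin slope as a cross-check), and prints the
chamber resistance as a percentage of the coronary resistance per activity
state — the figure showing the chamber's contribution is negligible.
"""

from coroflow import (
    NoiseModel,
    characterize,
    generate_chamber_experiment,
    percent_table,
)

experiment = generate_chamber_experiment(noise=NoiseModel("gaussian_relative", 0.02, seed=42))

means = {}
print("chamber resistance estimates (dynes·s/cm⁵):")
for vessel, measurements in experiment.measurements.items():
    result = characterize(measurements)
    means[vessel] = result.mean_resistance
    print(f"  {vessel.value}: true {experiment.true_resistance[vessel]:6.0f}   "
          f"mean {result.mean_resistance:7.1f}   slope {result.slope_resistance:7.1f}   "
          f"({result.n_points} setpoints)")

print("\nchamber resistance as % of coronary resistance"
      " (R = rest, E1 = light, E2 = moderate exercise):")
print(percent_table(means, ndigits=2).to_string(index=False))
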