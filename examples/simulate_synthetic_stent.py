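"""Six-month degradation course of a synthetic two-ring scaffold.

Builds a ring-and-link strain field (crowns ~0.3, links ~0.12, bodies
~0.03), steps the damage law at dt = 0.5 days, and prints the monthly
summary: mass-loss ratio, alive-graph component count, the scaffold-capacity
surrogate, and the lumen-diameter trend it drives.
"""

from scaffold_degrade import (
    SimulationConfig,
    StentFieldSpec,
    generate_stent_field,
    lumen_trend,
    run,
    strain_histogram,
)

field = generate_stent_field(StentFieldSpec(seed=42))
print(f"synthetic field: {field.n_elements} elements")
print("mass fraction per strain interval:")
print(strain_histogram(field).to_string(float_format=lambda v: f"{v:.3f}"))

result = run(field, SimulationConfig(dt=0.5, horizon=180.0))
monthly = result.trajectory[result.trajectory.time_days % 30 == 0]
diam = lumen_trend(monthly.set_index("time_days").capacity,
                   {"deployed": 3.28, "unloaded": 3.0})

print("\n  day  mass loss  components  capacity  lumen (mm)")
for (_, row), d in zip(monthly.iterrows(), diam):
    print(f"{row.time_days:5.0f}   {row.mass_loss_ratio:7.1%}  {row.n_components:10.0f}"
          f"  {row.capacity:8.3f}  {d:9.2f}")

first = result.events[0]
print(f"\nfirst fracture: element {first.element_id} "
      f"(strain {first.strain:.3f}) at day {first.time_days:g}")
print("High-strain crowns fracture first; mass loss grows monotonically and")
print("the capacity surrogate drops to 0 once every hoop-wise load path breaks.")
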