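"""Generate a synthetic rescue network and solve it.

The generator emulates the case study's structure at arbitrary sizes:
integer demands per (area, class), road legs longer than helicopter legs,
and auto-sized capacities that keep the instance feasible but binding.
"""

from quakerescue import GeneratorConfig, ModelSpec, generate_instance, solve_single

config = GeneratorConfig(n_areas=10, n_temp=8, n_comp=6, seed=1)
instance = generate_instance(config)
print(f"{instance.name}: total demand {instance.total_demand()} casualties, "
      f"temp capacity {instance.temp_capacity:.0f}, comp capacity {instance.comp_capacity:.0f}")

plan = solve_single(instance, ModelSpec())
print(f"optimal f1 = {plan.f1:.2f}, f2 = {plan.f2:.2f}")
print(f"opened {len(plan.opened_temp_ids(instance))}/{instance.n_temp} temporary, "
      f"{len(plan.opened_comp_ids(instance))}/{instance.n_comp} comprehensive hospitals")
print()
print("Same seed + config always reproduces the same instance and plan.")
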