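"""Solve the packaged Yushu case study for minimum weighted deterioration.

The plan routes 3434 casualties (640 serious, 778 moderate, 2016 mild) from
eight towns through temporary hospitals to comprehensive hospitals.  f1 is
the priority-weighted total severity-score deterioration accumulated in
transit; f2 the total psychological burden-hours of the same plan.
"""

from quakerescue import ModelSpec, solve_single, yushu

instance = yushu()
plan = solve_single(instance, ModelSpec())

print(f"status: {plan.status}")
print(f"f1 (weighted deterioration) = {plan.f1:.2f}")
print(f"f2 (psychological burden-hours) = {plan.f2:.2f}")
print(f"open temporary hospitals: {', '.join(plan.opened_temp_ids(instance))}")
print(f"open comprehensive hospitals: {', '.join(plan.opened_comp_ids(instance))}")
print()
print("f1 is dimensionless (deterioration fraction x priority weight x casualties);")
print("lower is better.  Five of six temporary and three of four comprehensive")
print("hospitals suffice at nominal demand.")
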