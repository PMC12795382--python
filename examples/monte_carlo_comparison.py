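"""Why robust plans: Monte-Carlo feasibility under realized demand.

The deterministic plan covers the nominal counts exactly (zero slack), so
almost any realization with one cell above nominal breaks it.  The robust
plan at full budget covers the entire interval.  Feasibility here is the
fixed-plan notion: do the plan's stage-1 flows cover the realized demand
cell by cell?
"""

from quakerescue import UncertaintySpec, compare_models, yushu

instance = yushu()
report = compare_models(
    instance, UncertaintySpec(gamma=1.0, variability=0.05),
    n=50, seed=1, mode="fixed_plan",
)

print(f"50 demand realizations at 5% variability ({report.distribution})")
print(f"deterministic plan: feasible in {report.deterministic.feasible_count}/50")
print(f"robust plan (Gamma=1): feasible in {report.robust.feasible_count}/50")
print(f"robust nominal f1 = {report.robust.nominal_f1:.2f} "
      f"(vs deterministic {report.deterministic.nominal_f1:.2f})")
print()
print("The robust plan pays a higher planned deterioration but survives every")
print("realization; the deterministic plan fails whenever any of the 24 demand")
print("cells exceeds its nominal value.")
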