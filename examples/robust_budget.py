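"""Effect of the uncertainty budget on the robust optimum.

Casualty counts are only known as intervals [qbar - qhat, qbar + qhat] with
qhat a fraction (here 20%) of the nominal count.  The budget Gamma in [0, 1]
sets how much of the worst case the plan must cover: the demand constraint
right-hand side inflates to qbar + qhat * Gamma.  More protection costs more
deterioration.
"""

from quakerescue import ModelSpec, UncertaintySpec, solve_single, yushu

instance = yushu()
print("Gamma   f1 optimum   open temp hospitals")
for gamma in (0.0, 0.25, 0.5, 0.75, 1.0):
    spec = (
        ModelSpec()
        if gamma == 0
        else ModelSpec(mode="robust", uncertainty=UncertaintySpec(gamma, 0.20))
    )
    plan = solve_single(instance, spec)
    print(f"{gamma:5.2f}   {plan.f1:10.2f}   {len(plan.opened_temp_ids(instance))}")
print()
print("f1 rises monotonically with Gamma: hedging against more of the demand")
print("interval forces longer routes and, at high budgets, a sixth temporary")
print("hospital.")
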