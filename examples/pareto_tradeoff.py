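"""Trade-off between deterioration and psychological cost.

The two objectives conflict: the epsilon-constraint method minimizes f1
under a budget f2 <= eps, sweeping eps from the attainable minimum of f2 up
to the f2 incurred by the unconstrained f1 optimum.
"""

from quakerescue import pareto_front, yushu

instance = yushu()
front = pareto_front(instance, n_points=8)

print(f"anchors: f1* = {front.f1_star:.2f}, f2* = {front.f2_star:.2f}")
print()
print("   eps (f2 budget)        f1        f2 used")
for p in front.points:
    print(f"   {p.epsilon:12.2f}  {p.f1:10.2f}  {p.f2:12.2f}")
print()
print("Tightening the psychological-cost budget (smaller eps) forces higher")
print("deterioration; each row is a Pareto-efficient compromise a decision-maker")
print("can pick from.")
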