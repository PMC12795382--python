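# quakerescue

Bi-objective robust location–transportation planning for post-earthquake
casualty rescue.

After a major earthquake, casualties in the affected towns must be triaged,
moved by road to nearby temporary hospitals for initial treatment, and flown
on to comprehensive hospitals for definitive care — while the true casualty
counts are still unknown. `quakerescue` builds and solves the mixed-integer
optimization model for this two-echelon network: which candidate hospitals to
open and how many casualties of each triage class to send along each arc. It
is written for operations-research practitioners and emergency-logistics
researchers who want a tested, scriptable implementation of the model and its
surrounding experimental protocols.

## The model

Casualties are classified by Injury Severity Score into serious, moderate and
mild classes *s*, each with a priority weight ω_s, psychological burden
coefficients α_s (pre-treatment road leg) and β_s (post-treatment air leg,
α_s > β_s), and expected death times T′_s before and T″_s after initial
treatment (T″_s > T′_s). A casualty's condition deteriorates in transit
following a piecewise trajectory in the time *t* spent travelling:

```
p(t) = 0.5 (t/T)^2              t ≤ T
       1 − 0.5 e^{2(1 − t/T)}   t > T
```

which is continuous at t = T with value 0.5 and one-sided slopes 1/T —
deterioration accelerates early and saturates late. Stage-1 arcs use the
untreated horizon T′_s, stage-2 arcs the treated horizon T″_s.

With binary open decisions U_j (temporary) and V_k (comprehensive) and
integer flows x_ijs (area *i* → temporary *j*) and y_jks (temporary *j* →
comprehensive *k*), the two objectives are

- **f1** = Σ ω_s p_ijs x_ijs + Σ ω_s u_jks y_jks — total weighted
  severity-score deterioration;
- **f2** = Σ α_s t_ij x_ijs + Σ β_s t_jk y_jks — total psychological cost in
  burden-hours;

subject to hospital capacities, per-area vehicle fleets, per-hospital
helicopter fleets, open-facility linking, demand coverage and flow
conservation. Demand ambiguity is handled by a budget-of-uncertainty robust
counterpart: each count lives in [q̄ − q̂, q̄ + q̂] and the covering
constraint inflates to Σ_j x_ijs ≥ q̄_is + q̂_is Γ_s with budget Γ_s ∈ [0, 1].
The bi-objective trade-off is traced with the ε-constraint method (minimize
f1 subject to f2 ≤ ε). Models are solved to proven optimality with HiGHS via
`scipy.optimize.milp`.

## Worked example

The 2010 Yushu (Qinghai) earthquake case study ships as a built-in fixture:
8 towns, 6 candidate temporary and 4 candidate comprehensive hospitals, 3434
casualties.

```python
from quakerescue import ModelSpec, solve_single, yushu

instance = yushu()
plan = solve_single(instance, ModelSpec())
print(f"f1 = {plan.f1:.2f}, f2 = {plan.f2:.2f}")
print(plan.opened_temp_ids(instance), plan.opened_comp_ids(instance))
```

prints

```
f1 = 2413.50, f2 = 30244.58
['J1', 'J2', 'J3', 'J4', 'J5'] ['K1', 'K3', 'K4']
```

— the minimum attainable weighted deterioration at nominal demand is 2413.50
(dimensionless: deterioration fraction × priority weight × casualties),
achieved by opening five temporary and three comprehensive hospitals; that
plan costs 30244.58 psychological burden-hours. The same solve is available
from the shell:

```
quakerescue solve --instance yushu --objective f1
```

The `examples/` directory holds one short script per capability: the case
study, the robust budget sweep, the ε-constraint Pareto front, the
Monte-Carlo deterministic-vs-robust comparison, and the synthetic-instance
generator. The CLI mirrors the library (`solve`, `pareto`, `sweep`,
`compare`, `generate`, `validate`); every run writes a `manifest.json` so it
can be reproduced exactly.

## Documentation

`docs/methods.md` describes the model assumptions, parameter meanings and
defaults, the synthetic-data generator, numerical choices and known
limitations.
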