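# Methods

## Problem and assumptions

`quakerescue` plans post-earthquake casualty rescue on a three-tier chain:
disaster areas → temporary hospitals (road vehicles, initial treatment) →
comprehensive hospitals (helicopters, definitive care). The model decides
which candidate hospitals to open and the integer casualty flows per triage
class on every arc. Its assumptions, inherited from the problem setting:

- every casualty is picked up and passes through exactly one temporary
  hospital and (unless the mild-stay variant is on) exactly one
  comprehensive hospital;
- vehicles and helicopters are homogeneous with fixed capacities and
  constant speeds; fleets are finite (per area for vehicles, per temporary
  hospital for helicopters);
- treatment time at the temporary hospital is not modelled; its only effect
  is to lengthen the expected death horizon (T″ > T′) and lower the
  psychological burden coefficient (β < α);
- each facility type has a single capacity value, interpreted as casualties
  accommodated per facility (it is compared directly against casualty flows
  in the capacity constraints);
- deterioration on an arc depends only on that arc's travel time, not on
  time already accumulated upstream — the stage-1 and stage-2 coefficients
  are arc-separable, which keeps the model linear in the flows.

## Deterioration and psychological cost

The deterioration fraction after `t` hours in transit with expected death
time `T` is quadratic (`0.5 (t/T)^2`) up to `t = T` and exponential-saturating
(`1 − 0.5 e^{2(1−t/T)}`) beyond; the branches agree at 0.5 with common
one-sided slope `1/T`, so the trajectory is C1. It is increasing in `t`,
decreasing in `T`, and stays in `[0, 1)` (we clamp at the largest double
below 1 where the exponential underflows). At exactly `t = T` the quadratic
branch is used; the branches agree there. Deterioration is evaluated once per
arc and class (`p[i,j,s]` with horizon T′_s, `u[j,k,s]` with T″_s) and enters
the MILP as constants.

Psychological cost is linear in exposure: α_s burden per casualty-hour on
the pre-treatment road leg, β_s on the post-treatment air leg, with
α_s > β_s within each class and both coefficients strictly decreasing with
milder injury. Validation enforces these orderings.

## The MILP

Objectives f1 (priority-weighted total deterioration) and f2 (total
burden-hours) over binaries U_j, V_k and integer flows x_ijs, y_jks, with:
per-facility capacity linked to the open decision (flow into a closed
facility is zero; an open facility must receive at least one casualty, so
the open set is fully determined by the flows), per-area vehicle and
per-hospital helicopter fleet limits, demand coverage, and per-(hospital,
class) flow conservation. The second summation of each objective runs over
all classes — the only dimensionally consistent reading.

**Robust counterpart.** Demand q_is is interval data [q̄ − q̂, q̄ + q̂] with
q̂ = δ·q̄ (δ the "variability"). With budget Γ_s ∈ [0, 1] the covering
constraint becomes Σ_j x_ijs ≥ q̄_is + q̂_is Γ_s. The right-hand side is kept
fractional; no explicit rounding is applied — flow integrality enforces the
ceiling per (area, class). This convention reproduces published robust
optima at the 0.5-tolerance level without any tuning. Γ is accepted per
class but broadcast from a scalar by default. At Γ = 0 the robust model's
optimum coincides with the deterministic one (the "≥" binds down to "=" under
strictly positive objective coefficients); the constraint matrices differ
only in the demand rows' upper bounds.

**ε-constraint method.** The bi-objective model is scalarized by minimizing
f1 under f2 ≤ ε. The Pareto front sweeps ε over [min f2, f2 at the
unconstrained f1 optimum] (anchor solves at both ends); ε below min f2 is
proven infeasible.

**Mild-stay variant.** Conservation for the mild class relaxes to
Σ_k y_jkc ≤ Σ_i x_ijc: mild casualties may complete treatment at the
temporary hospital. Retained casualties still occupy temporary-hospital
capacity (x already counts them); only the helicopter and
comprehensive-hospital side relaxes. Since every stage-2 coefficient is
strictly positive, the variant's optimum transfers no mild casualties.

## Numerical choices

- Backend: HiGHS through `scipy.optimize.milp`; relative MIP gap 1e-9 by
  default, optional wall-clock limit. Models export to CPLEX LP format for
  cross-solver debugging.
- Every optimal plan is verified independently of the solver: flows are
  rounded to integers, constraint residuals must all be ≤ 1e-6, and f1/f2
  recomputed from the deterioration tables must agree with the solver
  objective within 1e-6; any violation downgrades the plan to an error
  status rather than reporting a doubtful optimum.
- Alternative optima: results are compared on objective values, not flow
  patterns. An optional lexicographic tie-break (secondary minimization of
  the opened-facility count at pinned objective) is available and off by
  default.
- The exhaustive oracle enumerates all integer demand splits (stars and
  bars) and is guarded to ≤ 12 casualties, ≤ 3 temporary and ≤ 2
  comprehensive hospitals; it prunes on the stage-1 partial objective, which
  is sound because stage-2 costs are nonnegative.
- Degenerate inputs: zero demands are allowed (their composition set is the
  single zero split); zero priority weights are allowed and give f1 = 0;
  travel times must be strictly positive.

## Case-study parameters

The packaged Yushu instance uses: weights ω = (3, 2, 1), α = (6, 2.5, 1.5),
β = (3.5, 1.5, 0.5), T′ = (1, 4, 12) h, T″ = (2, 8, 24) h for (serious,
moderate, mild); temporary capacity 850, comprehensive capacity 1200
casualties; 100 vehicles × 6 seats per area; 60 helicopters × 12 seats per
temporary hospital; demands 3434 casualties over 8 × 3 cells; road legs
2.33–4.86 h, air legs 0.55–2.40 h. Every road leg exceeds the serious
class's 1 h untreated horizon, so all serious stage-1 coefficients sit on
the exponential branch.

A worst-arc routing bound caps the psychological cost of any feasible plan:
routing every casualty over its longest stage-1 arc and the longest stage-2
arc gives f2 ≤ 51130.93 on this instance (`max_psych_cost`). The attainable
range of f2 computed by the anchor solves is [29229.08, 30244.58] at nominal
demand.

## Monte-Carlo evaluation

`sample_realizations` draws demand tables uniformly on the integers of
[⌊q̄ − q̂⌋, ⌈q̄ + q̂⌉], clipped at zero, reproducibly from a seed. The
uniform choice is ours; the sampling distribution is pluggable by replacing
this function. Two feasibility notions are provided because either is
defensible and they answer different questions:

- `fixed_plan` (default): a plan survives a realization iff its stage-1
  flows cover the realized demand cell by cell; all other constraints hold
  by construction. Under this notion the equality-built deterministic plan
  has zero slack and fails any realization with one cell above nominal,
  while the full-budget robust plan covers the whole interval by
  construction — the deterministic/robust contrast is exact.
- `fixed_locations`: the opened facilities are frozen and flows are
  re-optimized per realization, recording the re-solved objective or
  infeasibility. This measures the value of the location decision rather
  than of the whole plan, and yields per-realization objectives that exceed
  the nominal one on high-demand draws.

Neither mode is asserted to be "the" published protocol; within-interval
sampling cannot make a full-budget robust plan infeasible in `fixed_plan`
mode, so reported robust failure counts below n at Γ = 1 must stem from a
different sampling or feasibility notion.

## Synthetic instances

The generator emulates the case study's structure at arbitrary sizes:
per-class integer demand ranges defaulting to the case study's per-cell
spread (serious 40–140, moderate 60–140, mild 200–330), road-leg times
uniform on 2.3–4.9 h strictly above air-leg times on 0.5–2.2 h (the air
range is trimmed from the case study's 2.40 h maximum to keep the two legs
strictly separated), class parameters defaulting to the case-study values,
and `"auto"` capacities sized so aggregate through-capacity is 1.25× total
demand — feasible but binding. Generation is a pure function of the
configuration including its seed.

What the generator does **not** emulate: spatial correlation between travel
times (each arc is drawn independently), correlation between an area's
demand and its distance to hospitals, heterogeneous fleets, or road-damage
structure. Tests passing on synthetic instances therefore certify the
optimization machinery and its monotonicity/conservation properties, not the
realism of any particular rescue scenario.

## Problem sizes used in the shipped experiments

The test suite and the results script use the 8×6×4 case study (solves in
well under a second), a 3×3×2 generated network for multi-solve protocols,
seeded tiny instances (≤ 8 casualties, ≤ 3×2 facilities) for the
enumeration oracle, and a 15×12×10 scale smoke test. Monte-Carlo comparisons
use 50 realizations.

## Known limitations

- Single-period, single-commodity: no routing/scheduling of individual
  vehicles, no treatment queues, no multi-period dynamics.
- Uncertainty only in casualty counts; travel times, capacities and facility
  availability are deterministic.
- The budget-of-uncertainty counterpart protects against interval demand
  without distributional information; it can be conservative, and no
  distributionally robust variant is provided.
- Psychological cost is linear in time and headcount; no saturation or
  interaction effects.
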