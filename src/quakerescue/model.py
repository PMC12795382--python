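"""Deterministic and robust location-transportation MILPs.

The planning problem opens temporary hospitals ``U_j`` and comprehensive
hospitals ``V_k`` and routes integer casualty flows ``x[i,j,s]`` (road) and
``y[j,k,s]`` (air) to minimize either

* ``f1`` — total priority-weighted severity-score deterioration,
  ``sum_s w_s (sum_ij p[i,j,s] x[i,j,s] + sum_jk u[j,k,s] y[j,k,s])``, or
* ``f2`` — total psychological cost,
  ``sum_ijs alpha_s t_ij x[i,j,s] + sum_jks beta_s t_jk y[j,k,s]``,

subject to facility capacities, per-area vehicle fleets, per-hospital
helicopter fleets, open-facility linking, demand coverage and stage-to-stage
flow conservation.  Demand uncertainty is handled by a budget-of-uncertainty
robust counterpart: each (area, class) demand lives in the interval
``[qbar - qhat, qbar + qhat]`` and the covering right-hand side inflates to
``qbar + qhat * Gamma`` with budget ``Gamma`` in [0, 1].  The robust RHS is
kept fractional; the integrality of the flows enforces the ceiling.

The bi-objective trade-off is explored with the epsilon-constraint method:
minimize ``f1`` subject to ``f2 <= eps``, sweeping ``eps`` over the attainable
range of ``f2`` to trace the Pareto front.

Solved with HiGHS via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .deterioration import DeteriorationTables, build_deterioration_tables
from .domain import RescueInstance, RescuePlan

#: absolute agreement required between the solver objective and an
#: independent recomputation from the integer flows
OBJECTIVE_AGREEMENT_TOL = 1e-6
#: constraint residual tolerance for a plan reported optimal
RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class UncertaintySpec:
    """Budget-of-uncertainty description of demand ambiguity.

    ``gamma`` is the protection budget in [0, 1] — 0 reproduces the nominal
    model, 1 protects against the full interval top.  A scalar broadcasts to
    all classes; a sequence gives one budget per class.  ``variability`` is
    the half-width of the demand interval as a fraction of the nominal value,
    so the maximum deviation is ``qhat = variability * qbar``.
    """

    gamma: float | Sequence[float] = 0.0
    variability: float = 0.0

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.variability < 0:
            raise ValueError("variability must be >= 0")

    def gamma_per_class(self, n_classes: int) -> np.ndarray:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            return np.full(n_classes, g.item())
        if g.size != n_classes:
            raise ValueError(f"gamma has {g.size} entries for {n_classes} classes")
        return g

    def deviations(self, instance: RescueInstance) -> np.ndarray:
        """Maximum deviation ``qhat[i, s] = variability * qbar[i, s]``."""
        return self.variability * instance.demand.astype(float)

    def robust_rhs(self, instance: RescueInstance) -> np.ndarray:
        """Inflated covering requirement ``qbar + qhat * Gamma_s`` (fractional)."""
        g = self.gamma_per_class(instance.n_classes)
        return instance.demand + self.deviations(instance) * g[None, :]


def robust_demand(qbar: float, qhat: float, gamma: float) -> float:
    """Robust covering right-hand side ``qbar + qhat * gamma``.

    Used verbatim (fractional) as the RHS of the demand constraint; integer
    flows make the effective requirement its ceiling.
    """
    if qbar < 0 or qhat < 0:
        raise ValueError("demand and deviation must be nonnegative")
    if not 0 <= gamma <= 1:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    return qbar + qhat * gamma


@dataclass(frozen=True)
class SolverOptions:
    """Backend controls: relative MIP gap, wall-clock limit (s), backend name."""

    mip_rel_gap: float = 1e-9
    time_limit: float | None = None
    backend: str = "highs"


@dataclass(frozen=True)
class ModelSpec:
    """What to build and solve.

    ``mode`` selects the demand constraint: strict equality (deterministic)
    or the inflated ``>=`` robust counterpart.  ``objective`` is ``"f1"``,
    ``"f2"`` or ``"epsilon_constrained"`` (minimize f1 with ``f2 <= epsilon``).
    ``variant_mild_stay`` relaxes flow conservation for the mild class so mild
    casualties may complete treatment at the temporary hospital.
    ``tie_break_facilities`` resolves alternative optima by a secondary solve
    that minimizes the number of opened facilities at (numerically) the same
    objective value; off by default.
    """

    mode: str = "deterministic"
    objective: str = "f1"
    epsilon: float | None = None
    uncertainty: UncertaintySpec | None = None
    variant_mild_stay: bool = False
    tie_break_facilities: bool = False
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.mode not in ("deterministic", "robust"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.objective not in ("f1", "f2", "epsilon_constrained"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "epsilon_constrained" and self.epsilon is None:
            raise ValueError("epsilon_constrained objective requires epsilon")
        if self.objective != "epsilon_constrained" and self.epsilon is not None:
            raise ValueError("epsilon given but objective is not epsilon_constrained")
        if self.mode == "robust" and self.uncertainty is None:
            raise ValueError("robust mode requires an UncertaintySpec")


class MilpModel:
    """A solver-ready model: variable index map, objective vectors for both
    objectives, and the stacked linear constraints."""

    def __init__(self, instance: RescueInstance, spec: ModelSpec,
                 tables: DeteriorationTables):
        self.instance = instance
        self.spec = spec
        self.tables = tables
        I, J, K, S = instance.n_areas, instance.n_temp, instance.n_comp, instance.n_classes
        self.nU, self.nV = J, K
        self.nx, self.ny = I * J * S, J * K * S
        self.n = self.nU + self.nV + self.nx + self.ny
        self._build()

    # variable offsets -----------------------------------------------------
    def iU(self, j: int) -> int:
        return j

    def iV(self, k: int) -> int:
        return self.nU + k

    def ix(self, i: int, j: int, s: int) -> int:
        J, S = self.instance.n_temp, self.instance.n_classes
        return self.nU + self.nV + (i * J + j) * S + s

    def iy(self, j: int, k: int, s: int) -> int:
        K, S = self.instance.n_comp, self.instance.n_classes
        return self.nU + self.nV + self.nx + (j * K + k) * S + s

    def split(self, z: np.ndarray):
        """Split a flat solution vector into (U, V, x, y) integer arrays."""
        inst = self.instance
        U = np.rint(z[: self.nU]).astype(int)
        V = np.rint(z[self.nU : self.nU + self.nV]).astype(int)
        x = np.rint(z[self.nU + self.nV : self.nU + self.nV + self.nx]).astype(int)
        y = np.rint(z[self.nU + self.nV + self.nx :]).astype(int)
        return (
            U,
            V,
            x.reshape(inst.n_areas, inst.n_temp, inst.n_classes),
            y.reshape(inst.n_temp, inst.n_comp, inst.n_classes),
        )

    # construction ---------------------------------------------------------
    def _build(self) -> None:
        inst, spec = self.instance, self.spec
        I, J, K, S = inst.n_areas, inst.n_temp, inst.n_comp, inst.n_classes
        w = inst.weights

        self.c_f1 = np.zeros(self.n)
        self.c_f2 = np.zeros(self.n)
        for i, j, s in np.ndindex(I, J, S):
            self.c_f1[self.ix(i, j, s)] = w[s] * self.tables.p[i, j, s]
            self.c_f2[self.ix(i, j, s)] = inst.classes[s].alpha * inst.stage1_time[i, j]
        for j, k, s in np.ndindex(J, K, S):
            self.c_f1[self.iy(j, k, s)] = w[s] * self.tables.u[j, k, s]
            self.c_f2[self.iy(j, k, s)] = inst.classes[s].beta * inst.stage2_time[j, k]

        rows: list[np.ndarray] = []
        lo: list[float] = []
        hi: list[float] = []
        names: list[str] = []

        def add(coeffs: dict[int, float], lb: float, ub: float, name: str) -> None:
            r = np.zeros(self.n)
            for idx, v in coeffs.items():
                r[idx] = v
            rows.append(r)
            lo.append(lb)
            hi.append(ub)
            names.append(name)

        # temporary-hospital capacity, linked to the open decision
        for j in range(J):
            d = {self.ix(i, j, s): 1.0 for i in range(I) for s in range(S)}
            d[self.iU(j)] = -inst.temp_capacity
            add(d, -np.inf, 0.0, f"cap_temp[{inst.temp_hospitals[j]}]")
        # comprehensive-hospital capacity, linked to the open decision
        for k in range(K):
            d = {self.iy(j, k, s): 1.0 for j in range(J) for s in range(S)}
            d[self.iV(k)] = -inst.comp_capacity
            add(d, -np.inf, 0.0, f"cap_comp[{inst.comp_hospitals[k]}]")
        # per-area vehicle fleet
        for i in range(I):
            d = {self.ix(i, j, s): 1.0 for j in range(J) for s in range(S)}
            add(d, -np.inf, float(inst.vehicles[i] * inst.vehicle_capacity),
                f"fleet_vehicle[{inst.areas[i]}]")
        # per-temporary-hospital helicopter fleet
        for j in range(J):
            d = {self.iy(j, k, s): 1.0 for k in range(K) for s in range(S)}
            add(d, -np.inf, float(inst.helicopters[j] * inst.helicopter_capacity),
                f"fleet_helicopter[{inst.temp_hospitals[j]}]")
        # an opened facility must receive at least one casualty
        for j in range(J):
            d = {self.ix(i, j, s): -1.0 for i in range(I) for s in range(S)}
            d[self.iU(j)] = 1.0
            add(d, -np.inf, 0.0, f"open_link_temp[{inst.temp_hospitals[j]}]")
        for k in range(K):
            d = {self.iy(j, k, s): -1.0 for j in range(J) for s in range(S)}
            d[self.iV(k)] = 1.0
            add(d, -np.inf, 0.0, f"open_link_comp[{inst.comp_hospitals[k]}]")
        # demand coverage: equality in deterministic mode, inflated ">=" robust
        if spec.mode == "robust":
            rhs = spec.uncertainty.robust_rhs(inst)
        else:
            rhs = inst.demand.astype(float)
        for i in range(I):
            for s in range(S):
                d = {self.ix(i, j, s): 1.0 for j in range(J)}
                ub = np.inf if spec.mode == "robust" else rhs[i, s]
                add(d, rhs[i, s], ub,
                    f"demand[{inst.areas[i]},{inst.class_ids[s]}]")
        # flow conservation at temporary hospitals; with the mild-stay
        # variant, mild casualties may remain (outflow <= inflow)
        for j in range(J):
            for s in range(S):
                d = {self.ix(i, j, s): 1.0 for i in range(I)}
                for k in range(K):
                    d[self.iy(j, k, s)] = -1.0
                relax = spec.variant_mild_stay and inst.class_ids[s] == "mild"
                add(d, 0.0, np.inf if relax else 0.0,
                    f"conserve[{inst.temp_hospitals[j]},{inst.class_ids[s]}]")

        self.A = np.array(rows)
        self.c_lb = np.array(lo)
        self.c_ub = np.array(hi)
        self.row_names = names
        vlb = np.zeros(self.n)
        vub = np.full(self.n, np.inf)
        vub[: self.nU + self.nV] = 1.0
        self.bounds = Bounds(vlb, vub)
        self.integrality = np.ones(self.n)

        if self.spec.objective == "f2":
            self.c = self.c_f2
        else:
            self.c = self.c_f1
        if self.spec.objective == "epsilon_constrained":
            self.A = np.vstack([self.A, self.c_f2])
            self.c_lb = np.append(self.c_lb, -np.inf)
            self.c_ub = np.append(self.c_ub, float(self.spec.epsilon))
            self.row_names.append("psych_cost_budget")

    # residuals ------------------------------------------------------------
    def residuals(self, z: np.ndarray) -> np.ndarray:
        """Signed constraint violations (positive = violated) of a solution."""
        v = self.A @ z
        return np.maximum(self.c_lb - v, v - self.c_ub)

    # export ---------------------------------------------------------------
    def to_lp(self, path: str | Path) -> None:
        """Write the model in CPLEX LP format for cross-solver debugging."""
        inst = self.instance

        def vname(idx: int) -> str:
            if idx < self.nU:
                return f"U_{inst.temp_hospitals[idx]}"
            if idx < self.nU + self.nV:
                return f"V_{inst.comp_hospitals[idx - self.nU]}"
            if idx < self.nU + self.nV + self.nx:
                flat = idx - self.nU - self.nV
                s = flat % inst.n_classes
                i, j = divmod(flat // inst.n_classes, inst.n_temp)
                return f"x_{inst.areas[i]}_{inst.temp_hospitals[j]}_{inst.class_ids[s]}"
            flat = idx - self.nU - self.nV - self.nx
            s = flat % inst.n_classes
            j, k = divmod(flat // inst.n_classes, inst.n_comp)
            return f"y_{inst.temp_hospitals[j]}_{inst.comp_hospitals[k]}_{inst.class_ids[s]}"

        def expr(coeffs: np.ndarray) -> str:
            terms = []
            for idx in np.nonzero(coeffs)[0]:
                v = coeffs[idx]
                terms.append(f"{'+' if v >= 0 else '-'} {abs(v):.12g} {vname(idx)}")
            return " ".join(terms) if terms else "0 " + vname(0)

        lines = ["Minimize", f" obj: {expr(self.c)}", "Subject To"]
        r = 0
        for name, row, lb, ub in zip(self.row_names, self.A, self.c_lb, self.c_ub):
            tag = name.replace("[", "_").replace("]", "").replace(",", "_")
            if lb == ub:
                lines.append(f" c{r}_{tag}: {expr(row)} = {lb:.12g}")
                r += 1
            else:
                if np.isfinite(ub):
                    lines.append(f" c{r}_{tag}: {expr(row)} <= {ub:.12g}")
                    r += 1
                if np.isfinite(lb):
                    lines.append(f" c{r}_{tag}: {expr(row)} >= {lb:.12g}")
                    r += 1
        lines.append("Binary")
        lines.extend(f" {vname(i)}" for i in range(self.nU + self.nV))
        lines.append("General")
        lines.extend(f" {vname(i)}" for i in range(self.nU + self.nV, self.n))
        lines.append("End")
        Path(path).write_text("\n".join(lines) + "\n")


def build_model(instance: RescueInstance, spec: ModelSpec | None = None) -> MilpModel:
    """Assemble the MILP for an instance (deterioration tables included).

    If the aggregate feasibility pre-check fails the model is still built —
    the solver proves infeasibility — but the condition is detectable via
    :meth:`RescueInstance.feasibility_report`.
    """
    spec = spec or ModelSpec()
    tables = build_deterioration_tables(instance)
    return MilpModel(instance, spec, tables)


def evaluate_objectives(
    instance: RescueInstance,
    x: np.ndarray,
    y: np.ndarray,
    tables: DeteriorationTables | None = None,
) -> tuple[float, float]:
    """Recompute (f1, f2) from first principles, independent of any solver.

    ``x`` has shape (areas, temporary hospitals, classes) and ``y``
    (temporary, comprehensive, classes); a shape mismatch raises ValueError.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != (instance.n_areas, instance.n_temp, instance.n_classes):
        raise ValueError(f"x has shape {x.shape}, expected "
                         f"{(instance.n_areas, instance.n_temp, instance.n_classes)}")
    if y.shape != (instance.n_temp, instance.n_comp, instance.n_classes):
        raise ValueError(f"y has shape {y.shape}, expected "
                         f"{(instance.n_temp, instance.n_comp, instance.n_classes)}")
    tables = tables or build_deterioration_tables(instance)
    w = instance.weights
    f1 = float(
        (w[None, None, :] * tables.p * x).sum()
        + (w[None, None, :] * tables.u * y).sum()
    )
    alpha = np.array([c.alpha for c in instance.classes])
    beta = np.array([c.beta for c in instance.classes])
    f2 = float(
        (alpha[None, None, :] * instance.stage1_time[:, :, None] * x).sum()
        + (beta[None, None, :] * instance.stage2_time[:, :, None] * y).sum()
    )
    return f1, f2


def f1_class_components(
    instance: RescueInstance,
    x: np.ndarray,
    y: np.ndarray,
    tables: DeteriorationTables | None = None,
) -> np.ndarray:
    """Per-class contribution ``w_s (sum p x + sum u y)`` to f1 (post-hoc
    decomposition of a plan; the components sum to f1)."""
    tables = tables or build_deterioration_tables(instance)
    w = instance.weights
    return np.array(
        [
            float(w[s] * ((tables.p[:, :, s] * x[:, :, s]).sum()
                          + (tables.u[:, :, s] * y[:, :, s]).sum()))
            for s in range(instance.n_classes)
        ]
    )


def solve_single(instance: RescueInstance, spec: ModelSpec | None = None) -> RescuePlan:
    """Build and solve one model to proven optimality.

    The returned plan's objectives are recomputed independently of the solver
    and must agree with the solver objective within ``1e-6``; all constraint
    residuals of an optimal plan are verified below ``1e-6``.  A solver
    failure or disagreement yields ``status="error"``, never a silently
    sub-optimal "optimal" plan.
    """
    spec = spec or ModelSpec()
    model = build_model(instance, spec)
    plan = _solve_built(model)
    if plan.status == "optimal" and spec.tie_break_facilities:
        plan = _tie_break(model, plan)
    return plan


def _tie_break(model: MilpModel, plan: RescuePlan) -> RescuePlan:
    """Among the model's optimal plans, pick one opening fewest facilities.

    Re-solves with the original objective pinned to its optimum (within the
    agreement tolerance) and the opened-facility count as objective; the
    returned plan's objectives are re-evaluated as usual.
    """
    spec = model.spec
    pin = plan.f2 if spec.objective == "f2" else plan.f1
    A = np.vstack([model.A, model.c])
    c_lb = np.append(model.c_lb, -np.inf)
    c_ub = np.append(model.c_ub, pin + OBJECTIVE_AGREEMENT_TOL)
    c2 = np.zeros(model.n)
    c2[: model.nU + model.nV] = 1.0
    res = milp(
        c2,
        constraints=LinearConstraint(A, c_lb, c_ub),
        integrality=model.integrality,
        bounds=model.bounds,
        options={"mip_rel_gap": spec.solver.mip_rel_gap, "presolve": True},
    )
    if res.status != 0 or res.x is None:  # keep the original optimum
        return plan
    U, V, x, y = model.split(res.x)
    f1, f2 = evaluate_objectives(model.instance, x, y, model.tables)
    return RescuePlan(status="optimal", open_temp=U, open_comp=V, x=x, y=y,
                      f1=f1, f2=f2, gap=plan.gap)


def _solve_built(model: MilpModel) -> RescuePlan:
    spec = model.spec
    options: dict = {"mip_rel_gap": spec.solver.mip_rel_gap, "presolve": True}
    if spec.solver.time_limit is not None:
        options["time_limit"] = spec.solver.time_limit
    res = milp(
        model.c,
        constraints=LinearConstraint(model.A, model.c_lb, model.c_ub),
        integrality=model.integrality,
        bounds=model.bounds,
        options=options,
    )
    if res.status == 2:
        return RescuePlan(status="infeasible", message=res.message)
    if res.status != 0 or res.x is None:
        return RescuePlan(status="error", message=res.message)
    U, V, x, y = model.split(res.x)
    z = np.concatenate([U, V, x.ravel(), y.ravel()]).astype(float)
    worst = float(model.residuals(z).max())
    if worst > RESIDUAL_TOL:
        return RescuePlan(
            status="error",
            message=f"rounded solution violates a constraint by {worst:.3g}",
        )
    f1, f2 = evaluate_objectives(model.instance, x, y, model.tables)
    reported = f2 if spec.objective == "f2" else f1
    if abs(reported - res.fun) > OBJECTIVE_AGREEMENT_TOL:
        return RescuePlan(
            status="error",
            message=(
                f"independent objective recomputation {reported!r} disagrees "
                f"with solver objective {res.fun!r}"
            ),
        )
    return RescuePlan(
        status="optimal",
        open_temp=U,
        open_comp=V,
        x=x,
        y=y,
        f1=f1,
        f2=f2,
        gap=float(res.mip_gap) if res.mip_gap is not None else None,
    )


def solve_epsilon(instance: RescueInstance, spec: ModelSpec) -> RescuePlan:
    """Minimize f1 subject to ``f2 <= spec.epsilon`` (plus all model
    constraints); infeasible when epsilon is below the attainable minimum."""
    if spec.objective != "epsilon_constrained" or spec.epsilon is None:
        raise ValueError("solve_epsilon requires objective='epsilon_constrained' with epsilon set")
    return solve_single(instance, spec)


@dataclass
class ParetoPoint:
    epsilon: float
    f1: float | None
    f2: float | None
    status: str
    plan: RescuePlan


@dataclass
class ParetoFront:
    """Epsilon-sweep output: points sorted by epsilon plus the two anchors
    (unconstrained minima of f1 and of f2)."""

    points: list[ParetoPoint]
    f1_star: float
    f2_star: float
    f2_at_f1_opt: float

    def to_records(self) -> list[dict]:
        return [
            {"epsilon": p.epsilon, "f1": p.f1, "f2": p.f2, "status": p.status}
            for p in self.points
        ]


def pareto_front(
    instance: RescueInstance,
    spec: ModelSpec | None = None,
    epsilons: Iterable[float] | None = None,
    n_points: int = 10,
) -> ParetoFront:
    """Trace the Pareto front with the epsilon-constraint method.

    Anchor solves give ``f2*`` (min f2) and ``f1*`` (min f1, with the f2 it
    incurs); the default grid is ``n_points`` values spanning ``[f2*, f2 at
    the f1 optimum]``.  One epsilon-constrained solve per grid point; solver
    errors are recorded per point and the sweep continues.
    """
    base = spec or ModelSpec()
    anchor_f1 = solve_single(instance, replace(base, objective="f1", epsilon=None))
    anchor_f2 = solve_single(instance, replace(base, objective="f2", epsilon=None))
    if anchor_f1.status != "optimal" or anchor_f2.status != "optimal":
        raise RuntimeError("anchor solve failed; instance may be infeasible")
    if epsilons is None:
        epsilons = np.linspace(anchor_f2.f2, anchor_f1.f2, n_points)
    points = []
    for eps in sorted(epsilons):
        plan = solve_epsilon(
            instance, replace(base, objective="epsilon_constrained", epsilon=float(eps))
        )
        points.append(
            ParetoPoint(
                epsilon=float(eps),
                f1=plan.f1,
                f2=plan.f2,
                status=plan.status,
                plan=plan,
            )
        )
    return ParetoFront(
        points=points,
        f1_star=anchor_f1.f1,
        f2_star=anchor_f2.f2,
        f2_at_f1_opt=anchor_f1.f2,
    )


def max_psych_cost(instance: RescueInstance) -> float:
    """Upper bound on f2 over all feasible plans of the deterministic model.

    Every casualty travels exactly one stage-1 arc and one stage-2 arc, so
    routing each casualty over its most expensive arcs bounds the total:
    ``sum_is q[i,s] alpha_s max_j t_ij + sum_s (sum_i q[i,s]) beta_s max_jk t_jk``.
    """
    alpha = np.array([c.alpha for c in instance.classes])
    beta = np.array([c.beta for c in instance.classes])
    stage1 = float(
        (instance.demand * alpha[None, :] * instance.stage1_time.max(axis=1)[:, None]).sum()
    )
    stage2 = float((instance.demand.sum(axis=0) * beta).sum() * instance.stage2_time.max())
    return stage1 + stage2


# ---------------------------------------------------------------------------
# Exhaustive oracle for tiny instances

#: enumeration guards: refuse anything larger
BRUTE_FORCE_MAX_CASUALTIES = 12
BRUTE_FORCE_MAX_TEMP = 3
BRUTE_FORCE_MAX_COMP = 2


def _compositions(total: int, parts: int):
    """All ways to write ``total`` as an ordered sum of ``parts`` nonnegative
    integers (stars and bars)."""
    for bars in itertools.combinations(range(total + parts - 1), parts - 1):
        prev = -1
        out = []
        for b in bars:
            out.append(b - prev - 1)
            prev = b
        out.append(total + parts - 2 - prev)
        yield tuple(out)


def brute_force_solve(instance: RescueInstance) -> RescuePlan:
    """True optimum of the deterministic model by exhaustive enumeration.

    Enumerates every integer split of each (area, class) demand over the
    temporary hospitals and of each resulting (hospital, class) inflow over
    the comprehensive hospitals, applying all capacity, fleet and
    conservation constraints.  Guarded to tiny instances (total casualties
    <= 12, at most 3 temporary and 2 comprehensive hospitals); intended as an
    independent test oracle for the MILP.
    """
    inst = instance
    if inst.total_demand() > BRUTE_FORCE_MAX_CASUALTIES:
        raise ValueError("brute force guard: too many casualties")
    if inst.n_temp > BRUTE_FORCE_MAX_TEMP or inst.n_comp > BRUTE_FORCE_MAX_COMP:
        raise ValueError("brute force guard: too many facilities")
    I, J, K, S = inst.n_areas, inst.n_temp, inst.n_comp, inst.n_classes
    tables = build_deterioration_tables(inst)
    w = inst.weights

    cells = [(i, s) for i in range(I) for s in range(S)]
    x_options = [list(_compositions(int(inst.demand[i, s]), J)) for i, s in cells]

    best_f1 = math.inf
    best: tuple | None = None
    veh_cap = inst.vehicles * inst.vehicle_capacity
    heli_cap = inst.helicopters * inst.helicopter_capacity

    for combo in itertools.product(*x_options):
        x = np.zeros((I, J, S), dtype=int)
        for (i, s), alloc in zip(cells, combo):
            x[i, :, s] = alloc
        if (x.sum(axis=(1, 2)) > veh_cap).any():
            continue
        inflow_j = x.sum(axis=(0, 2))
        if (inflow_j > inst.temp_capacity).any():
            continue
        f1_stage1 = float((w[None, None, :] * tables.p * x).sum())
        if f1_stage1 >= best_f1:
            continue
        inflow_js = x.sum(axis=0)  # (J, S)
        y_options = [
            list(_compositions(int(inflow_js[j, s]), K))
            for j in range(J)
            for s in range(S)
        ]
        for ycombo in itertools.product(*y_options):
            y = np.zeros((J, K, S), dtype=int)
            for idx, (j, s) in enumerate((j, s) for j in range(J) for s in range(S)):
                y[j, :, s] = ycombo[idx]
            if (y.sum(axis=(1, 2)) > heli_cap).any():
                continue
            if (y.sum(axis=(0, 2)) > inst.comp_capacity).any():
                continue
            f1 = f1_stage1 + float((w[None, None, :] * tables.u * y).sum())
            if f1 < best_f1:
                best_f1 = f1
                best = (x.copy(), y.copy())

    if best is None:
        return RescuePlan(status="infeasible", message="enumeration found no feasible plan")
    x, y = best
    f1, f2 = evaluate_objectives(inst, x, y, tables)
    U = (x.sum(axis=(0, 2)) > 0).astype(int)
    V = (y.sum(axis=(0, 2)) > 0).astype(int)
    return RescuePlan(status="optimal", open_temp=U, open_comp=V, x=x, y=y,
                      f1=f1, f2=f2, gap=0.0)
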