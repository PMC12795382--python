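"""Experimental protocols: sweeps and Monte-Carlo robustness evaluation.

Four study designs over a rescue instance:

* :func:`weight_sweep` — how the triage priority weights shift the optimum
  and its per-class decomposition, across uncertainty settings;
* :func:`uncertainty_sweep` — optimal severity score as a function of the
  uncertainty budget and the demand variability;
* :func:`capacity_sweep` — sensitivity of the optimum to temporary- and
  comprehensive-hospital capacity, with finite-difference slopes so the two
  echelons can be compared;
* :func:`compare_models` — Monte-Carlo evaluation of the deterministic and
  robust plans against randomly realized demands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .domain import RescueInstance, RescuePlan
from .model import (
    ModelSpec,
    UncertaintySpec,
    evaluate_objectives,
    f1_class_components,
    solve_single,
)


@dataclass
class SweepCell:
    """One grid cell of a sweep: the setting, the solved plan and summaries."""

    setting: dict
    status: str
    f1: float | None = None
    f2: float | None = None
    components: np.ndarray | None = None  # per-class contribution to f1
    open_temp: list[str] = field(default_factory=list)
    open_comp: list[str] = field(default_factory=list)
    plan: RescuePlan | None = None


@dataclass
class SweepResult:
    """Sweep output: axis descriptors plus one record per grid cell (failed
    cells carry their status; values are never fabricated)."""

    axes: dict
    cells: list[SweepCell]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = dict(c.setting)
            row["status"] = c.status
            row["f1"] = c.f1
            row["f2"] = c.f2
            if c.components is not None:
                for cid, v in zip(self.axes.get("class_ids", []), c.components):
                    row[f"f1_{cid}"] = v
            row["open_temp"] = ",".join(c.open_temp)
            row["open_comp"] = ",".join(c.open_comp)
            rows.append(row)
        return pd.DataFrame(rows)


def with_weights(instance: RescueInstance, weights) -> RescueInstance:
    """Copy of an instance with the triage priority weights replaced."""
    classes = [dataclasses.replace(c, weight=float(w))
               for c, w in zip(instance.classes, weights)]
    return instance.replace(classes=classes)


def _spec_for(gamma: float, variability: float, base: ModelSpec | None = None) -> ModelSpec:
    base = base or ModelSpec()
    if gamma > 0:
        return replace(base, mode="robust",
                       uncertainty=UncertaintySpec(gamma=gamma, variability=variability))
    return replace(base, mode="deterministic", uncertainty=None)


def _solve_cell(instance: RescueInstance, spec: ModelSpec, setting: dict) -> SweepCell:
    plan = solve_single(instance, spec)
    if plan.status != "optimal":
        return SweepCell(setting=setting, status=plan.status, plan=plan)
    return SweepCell(
        setting=setting,
        status="optimal",
        f1=plan.f1,
        f2=plan.f2,
        components=f1_class_components(instance, plan.x, plan.y),
        open_temp=plan.opened_temp_ids(instance),
        open_comp=plan.opened_comp_ids(instance),
        plan=plan,
    )


def weight_sweep(
    instance: RescueInstance,
    weight_settings,
    uncertainty_grid=((0.0, 0.0),),
    base_spec: ModelSpec | None = None,
) -> SweepResult:
    """Minimize f1 for every (priority weights, Gamma, variability) cell.

    Each cell records total f1, the per-class decomposition of the optimal
    plan and the opened facilities.  ``weight_settings`` is an iterable of
    positive triples ordered (serious, moderate, mild); ``uncertainty_grid``
    of (gamma, variability) pairs, gamma = 0 meaning the deterministic model.
    """
    cells = []
    for weights in weight_settings:
        if any(w <= 0 for w in weights):
            raise ValueError(f"weights must be positive, got {weights}")
        winst = with_weights(instance, weights)
        for gamma, var in uncertainty_grid:
            setting = {"weights": tuple(weights), "gamma": gamma, "variability": var}
            cells.append(_solve_cell(winst, _spec_for(gamma, var, base_spec), setting))
    return SweepResult(
        axes={
            "weights": list(map(tuple, weight_settings)),
            "uncertainty": list(uncertainty_grid),
            "class_ids": instance.class_ids,
        },
        cells=cells,
    )


def uncertainty_sweep(
    instance: RescueInstance,
    gamma_grid,
    variability_grid,
    base_spec: ModelSpec | None = None,
) -> SweepResult:
    """Optimal f1 over a (Gamma, variability) grid of robust solves."""
    gamma_grid = list(gamma_grid)
    variability_grid = list(variability_grid)
    if any(not 0 <= g <= 1 for g in gamma_grid):
        raise ValueError("gamma grid must lie within [0, 1]")
    if any(not 0 <= d <= 0.5 for d in variability_grid):
        raise ValueError("variability grid must lie within [0, 0.5]")
    cells = []
    for gamma in gamma_grid:
        for var in variability_grid:
            setting = {"gamma": gamma, "variability": var}
            cells.append(_solve_cell(instance, _spec_for(gamma, var, base_spec), setting))
    return SweepResult(
        axes={"gamma": gamma_grid, "variability": variability_grid,
              "class_ids": instance.class_ids},
        cells=cells,
    )


def capacity_sweep(
    instance: RescueInstance,
    temp_capacity_grid=(),
    comp_capacity_grid=(),
    base_spec: ModelSpec | None = None,
) -> SweepResult:
    """Optimal f1 as each hospital capacity varies (one axis at a time).

    Cells where capacity drops below what demand requires are recorded as
    infeasible.  The result's ``axes`` carry finite-difference slopes
    ``df1/dC`` so the relative leverage of the two echelons is checkable.
    """
    cells = []
    for C in temp_capacity_grid:
        if C <= 0:
            raise ValueError("temporary-hospital capacity must be positive")
        mod = instance.replace(temp_capacity=float(C))
        cells.append(_solve_cell(mod, base_spec or ModelSpec(),
                                 {"axis": "temp_capacity", "value": float(C)}))
    for Q in comp_capacity_grid:
        if Q <= 0:
            raise ValueError("comprehensive-hospital capacity must be positive")
        mod = instance.replace(comp_capacity=float(Q))
        cells.append(_solve_cell(mod, base_spec or ModelSpec(),
                                 {"axis": "comp_capacity", "value": float(Q)}))

    def slopes(axis: str) -> list[float]:
        pts = [(c.setting["value"], c.f1) for c in cells
               if c.setting["axis"] == axis and c.status == "optimal"]
        pts.sort()
        return [
            (f1b - f1a) / (vb - va)
            for (va, f1a), (vb, f1b) in zip(pts, pts[1:])
            if vb != va
        ]

    return SweepResult(
        axes={
            "temp_capacity": list(temp_capacity_grid),
            "comp_capacity": list(comp_capacity_grid),
            "class_ids": instance.class_ids,
            "slopes_temp": slopes("temp_capacity"),
            "slopes_comp": slopes("comp_capacity"),
        },
        cells=cells,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo evaluation

def sample_realizations(
    instance: RescueInstance, variability: float, n: int, seed: int
) -> list[np.ndarray]:
    """Draw ``n`` random demand tables.

    Each count is uniform on the integers of ``[floor(qbar - qhat),
    ceil(qbar + qhat)]`` with ``qhat = variability * qbar``, clipped at zero;
    fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one realization")
    rng = np.random.default_rng(seed)
    qbar = instance.demand.astype(float)
    qhat = variability * qbar
    lo = np.clip(np.floor(qbar - qhat), 0, None).astype(int)
    hi = np.ceil(qbar + qhat).astype(int)
    return [rng.integers(lo, hi, endpoint=True) for _ in range(n)]


@dataclass
class ModelEvaluation:
    """Per-model Monte-Carlo outcome."""

    nominal_f1: float
    feasible_count: int
    mean_f1: float | None  # over feasible realizations only
    records: list[dict]


@dataclass
class EvaluationReport:
    """Deterministic-vs-robust Monte-Carlo comparison.

    ``mode="fixed_plan"`` scores a plan feasible on a realization iff its
    stage-1 flows cover the realized demand cell-by-cell (all other
    constraints hold by construction).  ``mode="fixed_locations"`` freezes
    the opened facilities and re-optimizes the flows against each realized
    demand, recording the re-solved objective or infeasibility.
    """

    n_realizations: int
    seed: int
    variability: float
    gamma: float
    mode: str
    distribution: str
    deterministic: ModelEvaluation
    robust: ModelEvaluation


def _fixed_locations_resolve(
    instance: RescueInstance, plan: RescuePlan, demand: np.ndarray
) -> RescuePlan:
    """Re-optimize flows for a realized demand with facilities frozen.

    Closed facilities are removed by shrinking their capacity link: we keep
    the instance intact and instead forbid flow into closed facilities via a
    zero-capacity override.
    """
    # encode frozen locations by zeroing capacity of closed facilities
    mod = instance.replace(demand=demand)
    spec = ModelSpec()
    from .model import build_model, _solve_built  # local import to avoid cycle

    model = build_model(mod, spec)
    ub = model.bounds.ub.copy()
    for j in range(instance.n_temp):
        ub[model.iU(j)] = float(plan.open_temp[j])
    for k in range(instance.n_comp):
        ub[model.iV(k)] = float(plan.open_comp[k])
    model.bounds.ub = ub
    return _solve_built(model)


def compare_models(
    instance: RescueInstance,
    uncertainty: UncertaintySpec,
    n: int = 50,
    seed: int = 0,
    mode: str = "fixed_plan",
) -> EvaluationReport:
    """Monte-Carlo comparison of the deterministic and robust plans.

    Solves both nominal plans, draws ``n`` demand realizations at the given
    variability, and scores each plan on each realization according to
    ``mode`` (see :class:`EvaluationReport`).  Bitwise reproducible from the
    arguments.
    """
    if mode not in ("fixed_plan", "fixed_locations"):
        raise ValueError(f"unknown mode {mode!r}")
    det_plan = solve_single(instance, ModelSpec())
    rob_plan = solve_single(
        instance, ModelSpec(mode="robust", uncertainty=uncertainty)
    )
    if rob_plan.status != "optimal":
        raise RuntimeError("robust model must be feasible for the comparison")
    realizations = sample_realizations(instance, uncertainty.variability, n, seed)

    def score(plan: RescuePlan) -> ModelEvaluation:
        records = []
        objs = []
        for r, demand in enumerate(realizations):
            if plan.status != "optimal":
                records.append({"realization": r, "feasible": False, "f1": None})
                continue
            if mode == "fixed_plan":
                covered = plan.x.sum(axis=1) >= demand
                feas = bool(covered.all())
                f1 = plan.f1 if feas else None
            else:
                resolved = _fixed_locations_resolve(instance, plan, demand)
                feas = resolved.status == "optimal"
                f1 = resolved.f1 if feas else None
            records.append({"realization": r, "feasible": feas, "f1": f1})
            if feas:
                objs.append(f1)
        return ModelEvaluation(
            nominal_f1=plan.f1 if plan.status == "optimal" else float("nan"),
            feasible_count=len(objs),
            mean_f1=float(np.mean(objs)) if objs else None,
            records=records,
        )

    g = uncertainty.gamma_per_class(instance.n_classes)
    return EvaluationReport(
        n_realizations=n,
        seed=seed,
        variability=uncertainty.variability,
        gamma=float(g[0]) if np.allclose(g, g[0]) else float("nan"),
        mode=mode,
        distribution="uniform integer on [floor(qbar-qhat), ceil(qbar+qhat)]",
        deterministic=score(det_plan),
        robust=score(rob_plan),
    )
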