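"""Domain types for a two-echelon casualty-rescue network.

A rescue instance describes a three-tier chain: disaster areas ``I`` where
casualties of three triage classes (serious / moderate / mild) await pickup,
candidate temporary hospitals ``J`` reached by road vehicle for initial
treatment, and candidate comprehensive hospitals ``K`` reached by helicopter
for definitive care.  All quantities live in physical units: casualties are
integer head counts, travel times are hours, capacities are casualties per
facility, and each triage class carries a priority weight, psychological
burden coefficients for the two transport stages, and expected death times
before and after initial treatment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: canonical triage class order used throughout the package
CLASS_IDS = ("serious", "moderate", "mild")


class ValidationError(ValueError):
    """An instance or plan violates a structural invariant.

    The message names the offending field so malformed input files can be
    fixed without reading source code.
    """


@dataclass(frozen=True)
class CasualtyClassParams:
    """Parameters of one triage class.

    Attributes
    ----------
    class_id:
        One of ``"serious"``, ``"moderate"``, ``"mild"``.
    weight:
        Dimensionless priority weight applied to this class's severity-score
        deterioration in the main objective.
    alpha:
        Psychological burden per casualty-hour during the road leg
        (area -> temporary hospital), before any treatment.
    beta:
        Psychological burden per casualty-hour during the air leg
        (temporary -> comprehensive hospital), after initial treatment.
        Treatment relieves distress, so ``alpha > beta``.
    t_death_untreated:
        Expected death time in hours for an untreated casualty of this class.
    t_death_treated:
        Expected death time in hours after initial treatment; treatment
        extends the horizon, so ``t_death_treated > t_death_untreated``.
    """

    class_id: str
    weight: float
    alpha: float
    beta: float
    t_death_untreated: float
    t_death_treated: float

    def validate(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValidationError(
                f"class_id must be one of {CLASS_IDS}, got {self.class_id!r}"
            )
        if not self.t_death_treated > self.t_death_untreated > 0:
            raise ValidationError(
                f"class {self.class_id}: need t_death_treated > t_death_untreated > 0, "
                f"got {self.t_death_treated} and {self.t_death_untreated}"
            )
        if not self.alpha > self.beta > 0:
            raise ValidationError(
                f"class {self.class_id}: need alpha > beta > 0, "
                f"got alpha={self.alpha}, beta={self.beta}"
            )
        if self.weight < 0:
            raise ValidationError(f"class {self.class_id}: weight must be >= 0")


@dataclass
class RescueInstance:
    """Full parameterization of one rescue network.

    Arrays are indexed positionally: ``demand[i, s]`` is the nominal casualty
    count of class ``classes[s]`` in area ``areas[i]``; ``stage1_time[i, j]``
    and ``stage2_time[j, k]`` are complete travel-time matrices in hours.
    """

    areas: list[str]
    temp_hospitals: list[str]
    comp_hospitals: list[str]
    classes: list[CasualtyClassParams]
    demand: np.ndarray  # (|I|, |S|) nonnegative integers
    vehicles: np.ndarray  # (|I|,) vehicles stationed per area
    helicopters: np.ndarray  # (|J|,) helicopters per temporary hospital
    vehicle_capacity: int  # casualties per vehicle
    helicopter_capacity: int  # casualties per helicopter
    temp_capacity: float  # casualties per temporary hospital
    comp_capacity: float  # casualties per comprehensive hospital
    stage1_time: np.ndarray  # (|I|, |J|) hours
    stage2_time: np.ndarray  # (|J|, |K|) hours
    name: str = "instance"

    def __post_init__(self) -> None:
        self.demand = np.asarray(self.demand)
        self.vehicles = np.asarray(self.vehicles)
        self.helicopters = np.asarray(self.helicopters)
        self.stage1_time = np.asarray(self.stage1_time, dtype=float)
        self.stage2_time = np.asarray(self.stage2_time, dtype=float)

    # -- sizes ------------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_temp(self) -> int:
        return len(self.temp_hospitals)

    @property
    def n_comp(self) -> int:
        return len(self.comp_hospitals)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_ids(self) -> list[str]:
        return [c.class_id for c in self.classes]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes], dtype=float)

    def total_demand(self) -> int:
        return int(self.demand.sum())

    def replace(self, **changes) -> "RescueInstance":
        """Copy with selected fields overridden (validated by the caller)."""
        return dataclasses.replace(self, **changes)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError on the
        first violation, naming the offending field."""
        for c in self.classes:
            c.validate()
        if len(set(self.class_ids)) != len(self.classes):
            raise ValidationError("classes: duplicate class_id")
        # cross-class ordering of psychological burden: more severe injuries
        # carry a strictly heavier burden in both stages
        order = {cid: i for i, cid in enumerate(CLASS_IDS)}
        by_sev = sorted(self.classes, key=lambda c: order[c.class_id])
        for worse, milder in zip(by_sev, by_sev[1:]):
            if not (worse.alpha > milder.alpha and worse.beta > milder.beta):
                raise ValidationError(
                    f"classes: psychological coefficients must strictly decrease "
                    f"with milder injury ({worse.class_id} vs {milder.class_id})"
                )

        if self.demand.shape != (self.n_areas, self.n_classes):
            raise ValidationError(
                f"demand: expected shape {(self.n_areas, self.n_classes)}, "
                f"got {self.demand.shape}"
            )
        if not np.issubdtype(self.demand.dtype, np.integer):
            if not np.all(self.demand == np.rint(self.demand)):
                raise ValidationError("demand: casualty counts must be integers")
            self.demand = self.demand.astype(int)
        if (self.demand < 0).any():
            i, s = np.argwhere(self.demand < 0)[0]
            raise ValidationError(
                f"demand[{self.areas[i]}, {self.class_ids[s]}]: negative count"
            )

        if self.stage1_time.shape != (self.n_areas, self.n_temp):
            raise ValidationError(
                f"stage1_time: expected shape {(self.n_areas, self.n_temp)}, "
                f"got {self.stage1_time.shape}"
            )
        if self.stage2_time.shape != (self.n_temp, self.n_comp):
            raise ValidationError(
                f"stage2_time: expected shape {(self.n_temp, self.n_comp)}, "
                f"got {self.stage2_time.shape}"
            )
        for nm, mat in (("stage1_time", self.stage1_time), ("stage2_time", self.stage2_time)):
            if not np.isfinite(mat).all():
                raise ValidationError(f"{nm}: missing or non-finite travel time")
            if (mat <= 0).any():
                raise ValidationError(f"{nm}: travel times must be strictly positive")

        if self.vehicles.shape != (self.n_areas,):
            raise ValidationError("vehicles: one entry per disaster area required")
        if self.helicopters.shape != (self.n_temp,):
            raise ValidationError("helicopters: one entry per temporary hospital required")
        for nm, val in (
            ("vehicle_capacity", self.vehicle_capacity),
            ("helicopter_capacity", self.helicopter_capacity),
            ("temp_capacity", self.temp_capacity),
            ("comp_capacity", self.comp_capacity),
        ):
            if val <= 0:
                raise ValidationError(f"{nm}: must be positive, got {val}")
        if (self.vehicles <= 0).any() or (self.helicopters <= 0).any():
            raise ValidationError("fleet sizes must be positive integers")

    def feasibility_report(self) -> dict:
        """Aggregate capacity pre-check (reported, never silently assumed).

        Compares total nominal demand against system through-capacity at each
        echelon and each area's demand against its vehicle fleet.  A failing
        check does not prove infeasibility of a *robust* model (which inflates
        demand further), but a passing one is necessary for the nominal model.
        """
        total = self.total_demand()
        temp_through = sum(
            min(self.temp_capacity, h * self.helicopter_capacity)
            for h in self.helicopters
        )
        comp_cap = self.n_comp * self.comp_capacity
        per_area = self.demand.sum(axis=1)
        fleet_ok = per_area <= self.vehicles * self.vehicle_capacity
        checks = {
            "temp_echelon_ok": bool(total <= temp_through),
            "comp_echelon_ok": bool(total <= comp_cap),
            "area_fleet_ok": {
                self.areas[i]: bool(fleet_ok[i]) for i in range(self.n_areas)
            },
        }
        checks["feasible"] = (
            checks["temp_echelon_ok"]
            and checks["comp_echelon_ok"]
            and all(fleet_ok)
        )
        return checks

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "areas": self.areas,
            "temp_hospitals": self.temp_hospitals,
            "comp_hospitals": self.comp_hospitals,
            "classes": [dataclasses.asdict(c) for c in self.classes],
            "demand": {
                a: {cid: int(self.demand[i, s]) for s, cid in enumerate(self.class_ids)}
                for i, a in enumerate(self.areas)
            },
            "vehicles": {a: int(v) for a, v in zip(self.areas, self.vehicles)},
            "helicopters": {j: int(h) for j, h in zip(self.temp_hospitals, self.helicopters)},
            "vehicle_capacity": int(self.vehicle_capacity),
            "helicopter_capacity": int(self.helicopter_capacity),
            "temp_capacity": float(self.temp_capacity),
            "comp_capacity": float(self.comp_capacity),
            "stage1_time": {
                a: {j: float(self.stage1_time[i, jj]) for jj, j in enumerate(self.temp_hospitals)}
                for i, a in enumerate(self.areas)
            },
            "stage2_time": {
                j: {k: float(self.stage2_time[jj, kk]) for kk, k in enumerate(self.comp_hospitals)}
                for jj, j in enumerate(self.temp_hospitals)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RescueInstance":
        try:
            areas = list(d["areas"])
            temps = list(d["temp_hospitals"])
            comps = list(d["comp_hospitals"])
            classes = [CasualtyClassParams(**c) for c in d["classes"]]
            cids = [c.class_id for c in classes]
            demand = np.array(
                [[d["demand"][a][cid] for cid in cids] for a in areas]
            )
            stage1 = np.full((len(areas), len(temps)), np.nan)
            for i, a in enumerate(areas):
                for jj, j in enumerate(temps):
                    cell = d["stage1_time"].get(a, {}).get(j)
                    if cell is None:
                        raise ValidationError(f"stage1_time[{a}][{j}]: missing cell")
                    stage1[i, jj] = cell
            stage2 = np.full((len(temps), len(comps)), np.nan)
            for jj, j in enumerate(temps):
                for kk, k in enumerate(comps):
                    cell = d["stage2_time"].get(j, {}).get(k)
                    if cell is None:
                        raise ValidationError(f"stage2_time[{j}][{k}]: missing cell")
                    stage2[jj, kk] = cell
            inst = cls(
                areas=areas,
                temp_hospitals=temps,
                comp_hospitals=comps,
                classes=classes,
                demand=demand,
                vehicles=np.array([d["vehicles"][a] for a in areas]),
                helicopters=np.array([d["helicopters"][j] for j in temps]),
                vehicle_capacity=d["vehicle_capacity"],
                helicopter_capacity=d["helicopter_capacity"],
                temp_capacity=d["temp_capacity"],
                comp_capacity=d["comp_capacity"],
                stage1_time=stage1,
                stage2_time=stage2,
                name=d.get("name", "instance"),
            )
        except KeyError as e:
            raise ValidationError(f"missing required field {e.args[0]!r}") from e
        inst.validate()
        return inst


@dataclass
class RescuePlan:
    """A solved (or provably unsolvable) location-transportation plan.

    ``x[i, j, s]`` casualties of class ``s`` move area ``i`` -> temporary
    hospital ``j`` by vehicle; ``y[j, k, s]`` move on to comprehensive
    hospital ``k`` by helicopter.  ``open_temp`` / ``open_comp`` are the
    binary facility decisions.  ``f1`` is the weighted total severity-score
    deterioration; ``f2`` the total psychological cost (burden-hours).
    """

    status: str  # "optimal" | "infeasible" | "error"
    open_temp: np.ndarray | None = None  # (|J|,) 0/1
    open_comp: np.ndarray | None = None  # (|K|,) 0/1
    x: np.ndarray | None = None  # (|I|, |J|, |S|) integers
    y: np.ndarray | None = None  # (|J|, |K|, |S|) integers
    f1: float | None = None
    f2: float | None = None
    gap: float | None = None
    message: str = ""

    def opened_temp_ids(self, instance: RescueInstance) -> list[str]:
        return [j for jj, j in enumerate(instance.temp_hospitals) if self.open_temp[jj]]

    def opened_comp_ids(self, instance: RescueInstance) -> list[str]:
        return [k for kk, k in enumerate(instance.comp_hospitals) if self.open_comp[kk]]


# ---------------------------------------------------------------------------
# File I/O

def load_instance(path: str | Path) -> RescueInstance:
    """Load and validate a rescue instance.

    ``path`` may be a single JSON document or a directory holding a CSV
    bundle (one file per matrix) as written by :func:`save_instance`.
    """
    path = Path(path)
    if path.is_dir():
        return _load_csv_bundle(path)
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError(f"{path}: not valid JSON ({e})") from e
    return RescueInstance.from_dict(d)


def save_instance(instance: RescueInstance, path: str | Path, fmt: str = "json") -> None:
    """Write an instance as a JSON document (``fmt="json"``) or as a CSV
    bundle directory (``fmt="csv"``)."""
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(instance.to_dict(), fh, indent=1)
    elif fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            instance.demand, index=instance.areas, columns=instance.class_ids
        ).to_csv(path / "demand.csv")
        pd.DataFrame(
            instance.stage1_time, index=instance.areas, columns=instance.temp_hospitals
        ).to_csv(path / "stage1_time.csv")
        pd.DataFrame(
            instance.stage2_time, index=instance.temp_hospitals, columns=instance.comp_hospitals
        ).to_csv(path / "stage2_time.csv")
        pd.DataFrame(
            [dataclasses.asdict(c) for c in instance.classes]
        ).set_index("class_id").to_csv(path / "classes.csv")
        pd.DataFrame(
            {"vehicles": instance.vehicles}, index=instance.areas
        ).to_csv(path / "vehicles.csv")
        pd.DataFrame(
            {"helicopters": instance.helicopters}, index=instance.temp_hospitals
        ).to_csv(path / "helicopters.csv")
        with open(path / "scalars.json", "w") as fh:
            json.dump(
                {
                    "schema_version": SCHEMA_VERSION,
                    "name": instance.name,
                    "vehicle_capacity": int(instance.vehicle_capacity),
                    "helicopter_capacity": int(instance.helicopter_capacity),
                    "temp_capacity": float(instance.temp_capacity),
                    "comp_capacity": float(instance.comp_capacity),
                },
                fh,
                indent=1,
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _load_csv_bundle(path: Path) -> RescueInstance:
    def read(name, **kw):
        f = path / name
        if not f.exists():
            raise ValidationError(f"CSV bundle missing {name}")
        return pd.read_csv(f, index_col=0, **kw)

    demand = read("demand.csv")
    stage1 = read("stage1_time.csv")
    stage2 = read("stage2_time.csv")
    classes_df = read("classes.csv")
    vehicles = read("vehicles.csv")
    helicopters = read("helicopters.csv")
    with open(path / "scalars.json") as fh:
        scal = json.load(fh)
    if demand.isna().any().any() or stage1.isna().any().any() or stage2.isna().any().any():
        raise ValidationError("CSV bundle contains missing cells")
    classes = [
        CasualtyClassParams(class_id=str(cid), **row.to_dict())
        for cid, row in classes_df.iterrows()
    ]
    inst = RescueInstance(
        areas=[str(a) for a in demand.index],
        temp_hospitals=[str(j) for j in stage1.columns],
        comp_hospitals=[str(k) for k in stage2.columns],
        classes=classes,
        demand=demand[[c.class_id for c in classes]].to_numpy(),
        vehicles=vehicles["vehicles"].to_numpy(),
        helicopters=helicopters["helicopters"].to_numpy(),
        vehicle_capacity=scal["vehicle_capacity"],
        helicopter_capacity=scal["helicopter_capacity"],
        temp_capacity=scal["temp_capacity"],
        comp_capacity=scal["comp_capacity"],
        stage1_time=stage1.to_numpy(),
        stage2_time=stage2.to_numpy(),
        name=scal.get("name", path.name),
    )
    inst.validate()
    return inst


def save_plan(plan: RescuePlan, instance: RescueInstance, path: str | Path) -> None:
    """Write a machine-readable solution record.

    Produces ``<path>`` (JSON: status, objectives, open facilities, nonzero
    flows) and, for optimal plans, ``<path stem>_flows.csv`` — a flat per-arc
    flow table with one row per nonzero flow.
    """
    path = Path(path)
    if plan.status not in ("optimal", "infeasible"):
        raise ValueError(f"refusing to save plan with status {plan.status!r}")
    rec: dict = {"schema_version": SCHEMA_VERSION, "status": plan.status}
    rows = []
    if plan.status == "optimal":
        rec.update(
            f1=plan.f1,
            f2=plan.f2,
            gap=plan.gap,
            open_temp=plan.opened_temp_ids(instance),
            open_comp=plan.opened_comp_ids(instance),
        )
        flows: dict[str, dict] = {"x": {}, "y": {}}
        for (i, j, s), v in np.ndenumerate(plan.x):
            if v:
                key = f"{instance.areas[i]}|{instance.temp_hospitals[j]}|{instance.class_ids[s]}"
                flows["x"][key] = int(v)
                rows.append(
                    ("stage1", instance.areas[i], instance.temp_hospitals[j],
                     instance.class_ids[s], int(v), float(instance.stage1_time[i, j]))
                )
        for (j, k, s), v in np.ndenumerate(plan.y):
            if v:
                key = f"{instance.temp_hospitals[j]}|{instance.comp_hospitals[k]}|{instance.class_ids[s]}"
                flows["y"][key] = int(v)
                rows.append(
                    ("stage2", instance.temp_hospitals[j], instance.comp_hospitals[k],
                     instance.class_ids[s], int(v), float(instance.stage2_time[j, k]))
                )
        rec["flows"] = flows
    with open(path, "w") as fh:
        json.dump(rec, fh, indent=1)
    if plan.status == "optimal":
        pd.DataFrame(
            rows, columns=["stage", "origin", "destination", "class", "count", "time_h"]
        ).to_csv(path.with_name(path.stem + "_flows.csv"), index=False)


def load_plan(path: str | Path, instance: RescueInstance) -> RescuePlan:
    """Read a solution record written by :func:`save_plan`."""
    with open(path) as fh:
        rec = json.load(fh)
    if rec["status"] != "optimal":
        return RescuePlan(status=rec["status"])
    x = np.zeros((instance.n_areas, instance.n_temp, instance.n_classes), dtype=int)
    y = np.zeros((instance.n_temp, instance.n_comp, instance.n_classes), dtype=int)
    a_ix = {a: i for i, a in enumerate(instance.areas)}
    j_ix = {j: jj for jj, j in enumerate(instance.temp_hospitals)}
    k_ix = {k: kk for kk, k in enumerate(instance.comp_hospitals)}
    s_ix = {c: s for s, c in enumerate(instance.class_ids)}
    for key, v in rec["flows"]["x"].items():
        a, j, c = key.split("|")
        x[a_ix[a], j_ix[j], s_ix[c]] = v
    for key, v in rec["flows"]["y"].items():
        j, k, c = key.split("|")
        y[j_ix[j], k_ix[k], s_ix[c]] = v
    open_temp = np.zeros(instance.n_temp, dtype=int)
    for j in rec["open_temp"]:
        open_temp[j_ix[j]] = 1
    open_comp = np.zeros(instance.n_comp, dtype=int)
    for k in rec["open_comp"]:
        open_comp[k_ix[k]] = 1
    return RescuePlan(
        status="optimal",
        open_temp=open_temp,
        open_comp=open_comp,
        x=x,
        y=y,
        f1=rec["f1"],
        f2=rec["f2"],
        gap=rec.get("gap"),
    )
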