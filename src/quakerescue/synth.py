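"""Seeded generator of feasible random rescue instances.

Emulates the statistical structure of the packaged case study at arbitrary
sizes: integer casualty demands per (area, class), road legs markedly longer
than helicopter legs, and capacities sized so instances are feasible but
binding.  Intended for tests and scale experiments; generation is a pure
function of the configuration (including its seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .domain import CasualtyClassParams, RescueInstance, ValidationError
from .fixtures import yushu_classes


@dataclass
class GeneratorConfig:
    """Knobs of the random-instance generator.

    Demand ranges are closed integer intervals per class (ordered serious,
    moderate, mild), defaulting to the case study's per-cell spread.  Time
    ranges are hours; the road (stage-1) range sits strictly above the
    helicopter (stage-2) range, mirroring the case study (road legs
    2.33-4.86 h vs air legs 0.55-2.40 h).  Capacities and fleets may be fixed
    numbers or ``"auto"``, which sizes aggregate through-capacity to
    ``capacity_slack`` times total demand (1.05-1.5 keeps instances feasible
    but binding).
    """

    n_areas: int = 8
    n_temp: int = 6
    n_comp: int = 4
    demand_ranges: dict = field(
        default_factory=lambda: {
            "serious": (40, 140),
            "moderate": (60, 140),
            "mild": (200, 330),
        }
    )
    stage1_time_range: tuple[float, float] = (2.3, 4.9)
    stage2_time_range: tuple[float, float] = (0.5, 2.2)
    temp_capacity: float | str = "auto"
    comp_capacity: float | str = "auto"
    vehicles_per_area: int | str = "auto"
    helicopters_per_temp: int | str = "auto"
    vehicle_capacity: int = 6
    helicopter_capacity: int = 12
    capacity_slack: float = 1.25
    classes: list[CasualtyClassParams] = field(default_factory=yushu_classes)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_areas, self.n_temp, self.n_comp) < 1:
            raise ValueError("set sizes must be positive")
        for cid, (lo, hi) in self.demand_ranges.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"demand range for {cid} is empty or negative")
        for nm, (lo, hi) in (
            ("stage1_time_range", self.stage1_time_range),
            ("stage2_time_range", self.stage2_time_range),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{nm} must be positive and non-empty")
        if self.stage1_time_range[0] <= self.stage2_time_range[1]:
            raise ValueError(
                "road-leg times must sit strictly above helicopter-leg times"
            )
        if not 1.0 < self.capacity_slack:
            raise ValueError("capacity_slack must exceed 1 for feasibility")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "classes" in d:
            d["classes"] = [CasualtyClassParams(**c) for c in d["classes"]]
        if "demand_ranges" in d:
            d["demand_ranges"] = {k: tuple(v) for k, v in d["demand_ranges"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def generate_instance(config: GeneratorConfig) -> RescueInstance:
    """Draw one validated instance from the configuration.

    Demands and travel times are uniform over their configured ranges.
    ``"auto"`` capacities are sized from the realized total demand so the
    aggregate feasibility pre-check passes by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    I, J, K = config.n_areas, config.n_temp, config.n_comp
    cids = [c.class_id for c in config.classes]
    demand = np.column_stack(
        [
            rng.integers(*config.demand_ranges[cid], size=I, endpoint=True)
            for cid in cids
        ]
    )
    total = int(demand.sum())
    stage1 = np.round(rng.uniform(*config.stage1_time_range, size=(I, J)), 2)
    stage2 = np.round(rng.uniform(*config.stage2_time_range, size=(J, K)), 2)

    slack = config.capacity_slack
    temp_cap = (
        math.ceil(slack * total / J)
        if config.temp_capacity == "auto"
        else config.temp_capacity
    )
    comp_cap = (
        math.ceil(slack * total / K)
        if config.comp_capacity == "auto"
        else config.comp_capacity
    )
    per_area = demand.sum(axis=1)
    if config.vehicles_per_area == "auto":
        vehicles = np.ceil(slack * per_area / config.vehicle_capacity).astype(int)
    else:
        vehicles = np.full(I, int(config.vehicles_per_area))
    if config.helicopters_per_temp == "auto":
        helicopters = np.full(
            J, math.ceil(slack * total / (J * config.helicopter_capacity))
        )
    else:
        helicopters = np.full(J, int(config.helicopters_per_temp))

    inst = RescueInstance(
        areas=[f"I{i}" for i in range(1, I + 1)],
        temp_hospitals=[f"J{j}" for j in range(1, J + 1)],
        comp_hospitals=[f"K{k}" for k in range(1, K + 1)],
        classes=list(config.classes),
        demand=demand,
        vehicles=vehicles,
        helicopters=helicopters,
        vehicle_capacity=config.vehicle_capacity,
        helicopter_capacity=config.helicopter_capacity,
        temp_capacity=float(temp_cap),
        comp_capacity=float(comp_cap),
        stage1_time=stage1,
        stage2_time=stage2,
        name=f"synthetic-{I}x{J}x{K}-seed{config.seed}",
    )
    inst.validate()
    report = inst.feasibility_report()
    if not report["feasible"]:
        raise ValidationError(
            f"generated instance fails the feasibility pre-check: {report}"
        )
    return inst


def perturb_instance(instance: RescueInstance, variability: float, seed: int) -> RescueInstance:
    """Copy of an instance with demands resampled uniformly within
    ``[floor(qbar - qhat), ceil(qbar + qhat)]``, ``qhat = variability * qbar``;
    every other field untouched."""
    if variability < 0:
        raise ValueError("variability must be >= 0")
    from .experiments import sample_realizations

    demand = sample_realizations(instance, variability, 1, seed)[0]
    out = instance.replace(demand=demand, name=f"{instance.name}-perturbed")
    out.validate()
    return out
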