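"""Packaged case study: the 2010 Yushu (Qinghai) earthquake rescue network.

Eight affected towns (I1-I8), six health centers as candidate temporary
hospitals (J1-J6) and four large hospitals as candidate comprehensive
hospitals (K1-K4).  Casualty counts, road travel times and helicopter flight
times are the published case-study values; each area holds 100 rescue
vehicles carrying 6 casualties, each temporary hospital 60 helicopters
carrying 12.
"""

from __future__ import annotations

import numpy as np

from .domain import CasualtyClassParams, RescueInstance

# nominal casualties per (area, class): rows I1..I8, columns serious/moderate/mild
_DEMAND = [
    [137, 77, 214],
    [52, 134, 235],
    [78, 115, 228],
    [111, 88, 223],
    [122, 106, 202],
    [54, 72, 287],
    [46, 120, 298],
    [40, 66, 329],
]

# vehicle travel times area -> temporary hospital, hours (rows I1..I8, cols J1..J6)
_STAGE1_TIME = [
    [2.57, 3.17, 3.14, 4.13, 4.36, 4.53],
    [2.51, 3.11, 3.09, 3.98, 4.28, 4.55],
    [2.71, 3.31, 3.28, 3.27, 4.27, 4.45],
    [3.08, 3.00, 3.77, 3.12, 4.03, 4.42],
    [2.42, 3.18, 3.27, 3.38, 4.60, 4.78],
    [2.83, 3.30, 3.15, 3.22, 4.20, 4.50],
    [2.33, 3.55, 3.37, 3.67, 4.55, 4.86],
    [2.78, 3.15, 3.00, 3.50, 4.40, 4.75],
]

# helicopter flight times temporary -> comprehensive hospital, hours (J1..J6 x K1..K4)
_STAGE2_TIME = [
    [0.55, 0.98, 0.60, 0.78],
    [0.59, 2.34, 0.76, 0.80],
    [0.70, 2.40, 0.82, 0.85],
    [0.61, 2.36, 0.78, 0.81],
    [1.00, 1.26, 1.05, 1.24],
    [0.83, 2.18, 0.98, 1.17],
]


def yushu_classes() -> list[CasualtyClassParams]:
    """Triage-class parameters of the case study: priority weights (3, 2, 1),
    psychological burden coefficients alpha=(6, 2.5, 1.5) / beta=(3.5, 1.5, 0.5)
    and expected death times 1/4/12 h untreated, 2/8/24 h after treatment."""
    return [
        CasualtyClassParams("serious", weight=3, alpha=6.0, beta=3.5,
                            t_death_untreated=1.0, t_death_treated=2.0),
        CasualtyClassParams("moderate", weight=2, alpha=2.5, beta=1.5,
                            t_death_untreated=4.0, t_death_treated=8.0),
        CasualtyClassParams("mild", weight=1, alpha=1.5, beta=0.5,
                            t_death_untreated=12.0, t_death_treated=24.0),
    ]


def yushu() -> RescueInstance:
    """The packaged Yushu case-study instance (validated)."""
    inst = RescueInstance(
        areas=[f"I{i}" for i in range(1, 9)],
        temp_hospitals=[f"J{j}" for j in range(1, 7)],
        comp_hospitals=[f"K{k}" for k in range(1, 5)],
        classes=yushu_classes(),
        demand=np.array(_DEMAND, dtype=int),
        vehicles=np.full(8, 100, dtype=int),
        helicopters=np.full(6, 60, dtype=int),
        vehicle_capacity=6,
        helicopter_capacity=12,
        temp_capacity=850.0,
        comp_capacity=1200.0,
        stage1_time=np.array(_STAGE1_TIME),
        stage2_time=np.array(_STAGE2_TIME),
        name="yushu",
    )
    inst.validate()
    return inst
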