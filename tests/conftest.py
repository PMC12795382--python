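import numpy as np
import pytest

from quakerescue import CasualtyClassParams, RescueInstance, yushu


@pytest.fixture(scope="session")
def yushu_instance() -> RescueInstance:
    return yushu()


def serious_class(weight: float = 3.0) -> CasualtyClassParams:
    return CasualtyClassParams(
        "serious", weight=weight, alpha=6.0, beta=3.5,
        t_death_untreated=1.0, t_death_treated=2.0,
    )


def moderate_class(weight: float = 2.0) -> CasualtyClassParams:
    return CasualtyClassParams(
        "moderate", weight=weight, alpha=2.5, beta=1.5,
        t_death_untreated=4.0, t_death_treated=8.0,
    )


@pytest.fixture
def tiny_instance() -> RescueInstance:
    """One area with 3 serious casualties, two temporary hospitals (1.0 h
    and 2.0 h away), one comprehensive hospital 0.5 h onward, ample capacity.
    The optimum routes all three via the near hospital:
    f1 = 3 * 3 * (0.5 + 0.03125) = 4.78125 (verified by enumeration)."""
    inst = RescueInstance(
        areas=["I1"],
        temp_hospitals=["J1", "J2"],
        comp_hospitals=["K1"],
        classes=[serious_class()],
        demand=np.array([[3]]),
        vehicles=np.array([10]),
        helicopters=np.array([10, 10]),
        vehicle_capacity=6,
        helicopter_capacity=12,
        temp_capacity=100.0,
        comp_capacity=100.0,
        stage1_time=np.array([[1.0, 2.0]]),
        stage2_time=np.array([[0.5], [0.5]]),
        name="tiny",
    )
    inst.validate()
    return inst


def make_random_tiny(seed: int) -> RescueInstance:
    """Random instance small enough for exhaustive enumeration: up to 2 areas,
    3 temporary and 2 comprehensive hospitals, per-cell demand 0-2 (total
    <= 8).  Capacities are drawn so that some seeds are infeasible."""
    rng = np.random.default_rng(seed)
    I = int(rng.integers(1, 3))
    J = int(rng.integers(2, 4))
    K = int(rng.integers(1, 3))
    classes = [serious_class()] if rng.random() < 0.5 else [serious_class(), moderate_class()]
    S = len(classes)
    demand = rng.integers(0, 3, size=(I, S))
    if demand.sum() == 0:
        demand[0, 0] = 1
    inst = RescueInstance(
        areas=[f"I{i+1}" for i in range(I)],
        temp_hospitals=[f"J{j+1}" for j in range(J)],
        comp_hospitals=[f"K{k+1}" for k in range(K)],
        classes=classes,
        demand=demand,
        vehicles=np.full(I, int(rng.integers(1, 3))),
        helicopters=np.full(J, 1),
        vehicle_capacity=int(rng.integers(2, 7)),
        helicopter_capacity=int(rng.integers(2, 7)),
        temp_capacity=float(rng.integers(2, 9)),
        comp_capacity=float(rng.integers(2, 9)),
        stage1_time=np.round(rng.uniform(0.5, 3.5, size=(I, J)), 2),
        stage2_time=np.round(rng.uniform(0.3, 1.6, size=(J, K)), 2),
        name=f"tiny-random-{seed}",
    )
    inst.validate()
    return inst
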