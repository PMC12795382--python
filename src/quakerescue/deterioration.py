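"""Time-varying casualty deterioration and psychological transport cost.

A casualty's condition worsens along a piecewise trajectory governed by the
class-specific expected death time ``T``: slow-then-accelerating (quadratic)
while ``t <= T``, then decelerating towards total deterioration (exponential
saturation) for ``t > T``.  The two branches meet at ``p(T) = 0.5`` with a
common one-sided derivative ``1/T``, so the trajectory is C1 at the join.

Transport also imposes a psychological burden proportional to time in
transit: ``alpha_s * t`` per casualty on the pre-treatment road leg and
``beta_s * t`` on the post-treatment air leg, with ``alpha_s > beta_s``
because initial treatment relieves distress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import CasualtyClassParams, RescueInstance


def deterioration_rate(t, T):
    """Fraction of deterioration after ``t`` hours in transit, horizon ``T``.

    ``0.5 (t/T)^2`` for ``t <= T``, ``1 - 0.5 e^{2(1 - t/T)}`` beyond.
    Accepts scalars or arrays (broadcast); the result lies in ``[0, 1)``,
    is continuous and increasing in ``t`` and decreasing in ``T``.

    Raises
    ------
    ValueError
        If ``t < 0`` or ``T <= 0``.
    """
    t = np.asarray(t, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(t < 0):
        raise ValueError("transit time t must be >= 0")
    if np.any(T <= 0):
        raise ValueError("expected death time T must be > 0")
    r = t / T
    early = 0.5 * r**2
    late = 1.0 - 0.5 * np.exp(2.0 * (1.0 - r))
    out = np.where(r <= 1.0, early, late)
    # mathematically p < 1 for all finite t; keep the open interval even when
    # the exponential underflows to zero
    out = np.minimum(out, np.nextafter(1.0, 0.0))
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class DeteriorationTables:
    """Per-arc deterioration coefficients consumed by the linear model.

    ``p[i, j, s]``: deterioration of class ``s`` on the road leg area ``i`` ->
    temporary hospital ``j`` (pre-treatment horizon).  ``u[j, k, s]``: on the
    air leg temporary ``j`` -> comprehensive ``k`` (post-treatment horizon).
    """

    p: np.ndarray  # (|I|, |J|, |S|)
    u: np.ndarray  # (|J|, |K|, |S|)

    def to_frames(self, instance: RescueInstance) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Flat (arc, class, rate) tables for inspection / CSV export."""
        rows_p = [
            (instance.areas[i], instance.temp_hospitals[j], instance.class_ids[s], self.p[i, j, s])
            for (i, j, s) in np.ndindex(self.p.shape)
        ]
        rows_u = [
            (instance.temp_hospitals[j], instance.comp_hospitals[k], instance.class_ids[s], self.u[j, k, s])
            for (j, k, s) in np.ndindex(self.u.shape)
        ]
        cols = ["origin", "destination", "class", "rate"]
        return pd.DataFrame(rows_p, columns=cols), pd.DataFrame(rows_u, columns=cols)


def build_deterioration_tables(instance: RescueInstance) -> DeteriorationTables:
    """Evaluate the deterioration trajectory once per arc and class.

    Stage 1 uses each class's untreated horizon, stage 2 the post-treatment
    horizon (initial treatment at the temporary hospital markedly slows
    deterioration).  The model is linear in the flows, so these are plain
    objective coefficients.
    """
    T1 = np.array([c.t_death_untreated for c in instance.classes])
    T2 = np.array([c.t_death_treated for c in instance.classes])
    p = deterioration_rate(instance.stage1_time[:, :, None], T1[None, None, :])
    u = deterioration_rate(instance.stage2_time[:, :, None], T2[None, None, :])
    return DeteriorationTables(p=p, u=u)


def psych_unit_cost(stage: int, t: float, params: CasualtyClassParams) -> float:
    """Psychological burden-hours incurred per casualty on one arc.

    ``stage`` 1 is the road leg (coefficient ``alpha``), stage 2 the air leg
    (``beta``); total arc cost is unit cost times the flow on the arc.
    """
    if t <= 0:
        raise ValueError("transit time must be positive")
    if stage == 1:
        return params.alpha * t
    if stage == 2:
        return params.beta * t
    raise ValueError(f"stage must be 1 or 2, got {stage!r}")
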