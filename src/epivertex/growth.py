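"""Cell-cycle bookkeeping with mechanosensitive volume increments.

Each cell carries a cycle volume V that grows once per mechanical
interval and triggers division when it crosses the threshold V_d
(set to 1).  The per-interval increment is

    dV = max(0,  V_d * [beta + mu * (A - A_mean) / A0] * t_norm)

so larger-than-average cells progress faster (mechanosensing amplitude
``mu``, default 0.04) and the increment is clipped at zero: cells can
only grow or arrest, never regress.  ``t_norm`` converts the configured
growth-rate schedule into the per-interval normalization

    t_norm(k) = k * dt / (2 * V_d * beta),

under which a cell at the mean area needs V_d/2 (daughters restart at
V_d/2) and therefore divides with doubling time 1/k.  Two schedules are
supported: a constant rate k = 1/doubling_time (uniform-growth model,
~6 h), and the posterior-length-keyed exponential decay
k = k0 * exp(-delta_PL * L_p) used for the eye disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TissueState, cell_area


@dataclass
class GrowthParams:
    vd: float = 1.0                    # division threshold volume
    beta: float = 1.0                  # baseline increment rate
    mu: float = 0.04                   # mechanosensing amplitude
    schedule: str = "constant"         # "constant" | "exponential"
    doubling_time: float = 6.0         # hours (constant schedule)
    k0: float = 1.0 / 6.0              # initial growth rate, 1/h (exponential)
    delta_pl: float = 0.0              # decay per unit posterior length (exponential)
    mean_area_scope: str = "eligible"  # "eligible" | "all_active"

    def __post_init__(self) -> None:
        if self.vd <= 0 or self.beta <= 0 or self.mu < 0:
            raise ValueError("require vd > 0, beta > 0, mu >= 0")


def growth_rate(params: GrowthParams, posterior_length: float = 0.0) -> float:
    """Instantaneous growth rate k (1/h) of the configured schedule."""
    if params.schedule == "constant":
        return 1.0 / params.doubling_time
    if params.schedule == "exponential":
        if posterior_length < 0:
            raise ValueError("posterior length must be non-negative")
        return params.k0 * np.exp(-params.delta_pl * posterior_length)
    raise ValueError(f"unknown schedule {params.schedule!r}")


def t_norm(params: GrowthParams, posterior_length: float = 0.0, dt: float = 1.0) -> float:
    """Per-interval growth normalization t_norm(k) = k dt / (2 V_d beta)."""
    k = growth_rate(params, posterior_length)
    return k * dt / (2.0 * params.vd * params.beta)


def volume_increment(
    area: float,
    mean_area: float,
    params: GrowthParams,
    t_norm_value: float,
    a0: float = 1.0,
) -> float:
    """Clipped mechanosensitive volume increment for one interval."""
    raw = params.vd * (params.beta + params.mu * (area - mean_area) / a0) * t_norm_value
    return max(0.0, raw)


def eligible_cells(tissue: TissueState) -> list[int]:
    """Cells that progress through the cycle: active anterior cells.

    Cells in the morphogenetic furrow and posterior to it stop dividing
    the moment they enter the furrow."""
    return sorted(
        cid
        for cid, cell in tissue.cells.items()
        if cell.active and cell.region == "anterior"
    )


def initialize_cycle(tissue: TissueState, rng: np.random.Generator, params: GrowthParams) -> None:
    """Start every cell at a uniformly random point of its cycle,
    V ~ U(V_d/2, V_d), in increasing cell-id order (deterministic draws)."""
    for cid in sorted(tissue.cells):
        tissue.cells[cid].V = float(rng.uniform(0.5, 1.0)) * params.vd


def advance_cycle(
    tissue: TissueState,
    params: GrowthParams,
    dt: float,
    posterior_length: float = 0.0,
) -> list[int]:
    """Increment every eligible cell's volume for one interval.

    Returns the ids of cells whose volume reached V_d, in increasing id
    order (the order in which the caller should execute divisions)."""
    elig = eligible_cells(tissue)
    if not elig:
        return []
    if params.mean_area_scope == "all_active":
        scope = [cid for cid, c in tissue.cells.items() if c.active]
    else:
        scope = elig
    areas = {cid: cell_area(tissue, cid) for cid in set(elig) | set(scope)}
    mean_area = float(np.mean([areas[cid] for cid in scope]))
    tn = t_norm(params, posterior_length, dt)
    to_divide = []
    for cid in elig:
        cell = tissue.cells[cid]
        cell.V += volume_increment(areas[cid], mean_area, params, tn, a0=cell.A0)
        if cell.V >= params.vd:
            to_divide.append(cid)
    return to_divide
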