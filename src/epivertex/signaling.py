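"""Reaction-diffusion morphogen transport on the cell lattice and the
morphogenetic-furrow (MF) state machine.

A single effective transcription factor with an auto-activation loop,

    dc/dt = D_c * lap(c) + P_c * step(c - c0) - lambda * c,

is integrated on the lattice of cell centers.  The discrete Laplacian
treats the lattice as an approximate hexagonal packing with uniform
symmetric neighbor weights,

    lap(c)_i = 2 / (3 h^2) * sum_{j in N(i)} (c_j - c_i),

where h is the hexagonal lattice spacing inferred from the current
mean cell area (h^2 = 2 A_mean / sqrt(3)) and N(i) are the cells
sharing an edge with i; boundary cells simply use their existing
neighbors (zero-flux).  Because the discretization lives on the cell
adjacency graph rather than on physical distances, the emergent front
advances a fixed number of *cell rows* per unit time — so stronger
apical constriction (smaller cells) slows the front in physical units.

The wave is seeded by a posterior boundary flux: boundary cells in the
posterior 20% of the anterior-posterior extent receive a source equal
to 40% of the autoproduction rate until the flux cutoff time (10 h).
Cells whose concentration lies in the MF band [0.4, 1] form the
furrow: their preferred area is reduced by the apical constriction
factor and they stop dividing.  Cells leaving the band posteriorly get
their preferred area back and, after the differentiation delay
(2.5 h), are frozen out of the mechanical energy entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .mesh import TissueState, boundary_edges, cell_area, cell_centroid_safe as cell_centroid


@dataclass
class SignalingParams:
    diffusion: float = 0.7             # D_c, sim-length^2 / h
    production: float = 2.0            # P_c, 1/h
    threshold: float = 0.2             # c0, auto-activation threshold
    decay: float = 1.0                 # lambda, 1/h
    mf_lo: float = 0.4                 # MF concentration band
    mf_hi: float = 1.0
    constriction_factor: float = 0.15  # fraction in [0, 1): A0 -> A0*(1-f) in MF
    flux_fraction: float = 0.4         # boundary source = fraction * P_c
    flux_cutoff: float = 10.0          # hours; source ceases afterwards
    flux_region_fraction: float = 0.2  # x within this fraction of L_AP
    differentiation_delay: float = 2.5 # hours after exiting the MF

    def __post_init__(self) -> None:
        if not (0 <= self.constriction_factor < 1):
            raise ValueError("constriction factor must lie in [0, 1)")
        if self.mf_lo >= self.mf_hi:
            raise ValueError("MF band requires mf_lo < mf_hi")


# ----------------------------------------------------------------------
# lattice operators
# ----------------------------------------------------------------------
def _cell_index(tissue: TissueState) -> list[int]:
    return sorted(tissue.cells)


def lattice_weight(tissue: TissueState) -> float:
    """Uniform neighbor weight 2/(3 h^2) of the hexagonal approximation."""
    mean_area = float(np.mean([cell_area(tissue, cid) for cid in tissue.cells]))
    h2 = 2.0 * mean_area / np.sqrt(3.0)
    return 2.0 / (3.0 * h2)


def laplacian(
    tissue: TissueState, concentrations: dict[int, float], weight: float | None = None
) -> dict[int, float]:
    """Discrete Laplacian of a per-cell field (zero-flux at the boundary).

    ``weight`` pins the neighbor weight; by default it is derived from
    the current mean cell area.  Scenario drivers pin the weight at run
    start so the transport stays tied to the cell lattice and is
    independent of how packed the cells later become."""
    w = weight if weight is not None else lattice_weight(tissue)
    nmap = tissue.neighbors()
    out = {}
    for cid in tissue.cells:
        nbrs = nmap.get(cid, ())
        ci = concentrations[cid]
        out[cid] = w * sum(concentrations[j] - ci for j in nbrs) if nbrs else 0.0
    return out


def boundary_cells(tissue: TissueState) -> set[int]:
    emap = tissue.edge_cells()
    return {cids[0] for e, cids in emap.items() if len(cids) == 1}


def ap_extent(tissue: TissueState) -> tuple[float, float]:
    """(x_min, x_max) over used vertices; posterior sits at min x."""
    used = tissue.used_vertices()
    xs = tissue.vertices[used, 0]
    return float(xs.min()), float(xs.max())


def apply_boundary_flux(tissue: TissueState, params: SignalingParams, t: float) -> dict[int, float]:
    """Constant source terms for eligible posterior boundary cells.

    Eligible cells are boundary cells whose centroid x-coordinate lies
    within ``flux_region_fraction`` of the anterior-posterior length
    from the posterior edge; the source is ``flux_fraction * P_c``
    while t < flux_cutoff and zero afterwards."""
    if t >= params.flux_cutoff:
        return {}
    x_min, x_max = ap_extent(tissue)
    cutoff_x = x_min + params.flux_region_fraction * (x_max - x_min)
    src = params.flux_fraction * params.production
    out = {}
    for cid in boundary_cells(tissue):
        if cell_centroid(tissue, cid)[0] <= cutoff_x:
            out[cid] = src
    return out


def rd_step(
    tissue: TissueState, params: SignalingParams, dt: float, weight: float | None = None
) -> None:
    """Integrate the reaction-diffusion equation for one interval.

    The cell lattice is frozen during the step; concentrations are
    updated in place.  The step-function production is kept
    discontinuous; the integrator resolves threshold crossings with its
    own adaptive sub-steps.  See :func:`laplacian` for ``weight``."""
    ids = _cell_index(tissue)
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    w = weight if weight is not None else lattice_weight(tissue)
    nmap = tissue.neighbors()
    rows, cols = [], []
    for cid in ids:
        i = index[cid]
        for j in nmap.get(cid, ()):
            rows.append(i)
            cols.append(index[j])
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    deg = np.bincount(rows, minlength=n).astype(float)

    flux = np.zeros(n)
    t0 = tissue.time
    for cid, s in apply_boundary_flux(tissue, params, t0).items():
        flux[index[cid]] = s
    # a step never straddles the flux cutoff unnoticed: clip the source
    # to the sub-interval where it is on
    on_frac = 1.0
    if t0 < params.flux_cutoff < t0 + dt:
        on_frac = (params.flux_cutoff - t0) / dt

    D, P, c0, lam = params.diffusion, params.production, params.threshold, params.decay

    def rhs(t, c):
        neigh = np.zeros(n)
        np.add.at(neigh, rows, c[cols])
        lap = w * (neigh - deg * c)
        f = flux if (t - t0) < on_frac * dt else 0.0
        return D * lap + P * (c > c0) - lam * c + f

    c_init = np.array([tissue.cells[cid].c for cid in ids])
    sol = solve_ivp(rhs, (t0, t0 + dt), c_init, method="RK45",
                    rtol=1e-6, atol=1e-9, max_step=dt / 4.0)
    if not sol.success:
        raise RuntimeError(f"reaction-diffusion integration failed: {sol.message}")
    c_fin = sol.y[:, -1]
    for cid, val in zip(ids, c_fin):
        tissue.cells[cid].c = float(val)


# ----------------------------------------------------------------------
# MF membership, constriction, differentiation
# ----------------------------------------------------------------------
def update_mf_state(tissue: TissueState, params: SignalingParams) -> None:
    """Refresh region labels, apical constriction and differentiation.

    Cells inside the MF band are constricted and stop proliferating;
    cells exiting posteriorly (concentration above the band) regain
    their preferred area and are frozen ``differentiation_delay`` hours
    later; a cell dropping back below the band returns to the anterior
    pool."""
    t = tissue.time
    for cell in tissue.cells.values():
        if cell.region == "differentiated":
            continue
        if params.mf_lo <= cell.c <= params.mf_hi:
            cell.region = "MF"
            cell.A0 = cell.A0_ref * (1.0 - params.constriction_factor)
            cell.mf_exit_time = None
        elif cell.c > params.mf_hi:
            if cell.region != "posterior":
                cell.region = "posterior"
                cell.A0 = cell.A0_ref
                cell.mf_exit_time = t
        else:
            if cell.region == "MF":
                cell.A0 = cell.A0_ref
            cell.region = "anterior"
            cell.mf_exit_time = None
    for cell in tissue.cells.values():
        if (
            cell.region == "posterior"
            and cell.mf_exit_time is not None
            and t - cell.mf_exit_time >= params.differentiation_delay
        ):
            cell.region = "differentiated"
            cell.active = False


def mf_cells(tissue: TissueState) -> list[int]:
    return sorted(cid for cid, c in tissue.cells.items() if c.region == "MF")


def posterior_length(tissue: TissueState, band_fraction: float = 0.2) -> float:
    """Distance from the posterior edge midpoint to the MF midpoint.

    Both are measured along the anterior-posterior (x) axis within a
    central dorsal-ventral band (``band_fraction`` of the DV extent
    around the midline); the MF midpoint is the mean x of MF cell
    centroids in that band.  Returns 0 while the MF has not formed."""
    mf = mf_cells(tissue)
    if not mf:
        return 0.0
    used = tissue.used_vertices()
    ys = tissue.vertices[used, 1]
    y_mid = 0.5 * (float(ys.min()) + float(ys.max()))
    half_band = 0.5 * band_fraction * (float(ys.max()) - float(ys.min()))
    cents = {cid: cell_centroid(tissue, cid) for cid in mf}
    in_band = [cid for cid, g in cents.items() if abs(g[1] - y_mid) <= half_band]
    if not in_band:
        in_band = mf
    x_mf = float(np.mean([cents[cid][0] for cid in in_band]))
    bverts = {v for e in boundary_edges(tissue) for v in e}
    bcoords = tissue.vertices[np.array(sorted(bverts), dtype=int)]
    sel = np.abs(bcoords[:, 1] - y_mid) <= max(half_band, 1e-9)
    x_post = float(bcoords[sel, 0].min()) if sel.any() else float(bcoords[:, 0].min())
    return max(0.0, x_mf - x_post)
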