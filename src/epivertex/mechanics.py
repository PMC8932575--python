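"""Mechanical energy, forces, relaxation solvers and cellular pressure.

The tissue energy is the standard normalized vertex-model functional

    E' = sum_cells 1/2 (A'_a - A0'_a)^2
       + sum_edges  tension_ij * l'_ij
       + sum_cells  contractility/2 * L'_a^2

with every interior edge counted once, an elevated tension on boundary
edges, and differentiated (inactive) cells excluded from all three
terms.  Quasistatic dynamics assume mechanical relaxation is
instantaneous relative to growth and signaling: after every state
update the tissue is driven to the nearest local energy minimum
(quasi-Newton minimization of E' with its analytic gradient),
interleaved with topological transitions from :mod:`epivertex.topology`
until none fires.  An overdamped viscous integrator is provided as an
alternative solver; it takes a fixed number of explicit force steps per
mechanical interval and makes no convergence claim.

Cellular pressure follows the virial formula

    p_c = -(1/A_c) * sum_{i in c} dE_c/dr_i . (r_i - r_c)

evaluated on the cell's own energy terms.  Because each term is
translationally invariant and homogeneous in the vertex coordinates
(area of degree 2, lengths of degree 1), the sum collapses exactly to

    p_c = -2 K (A - A0) - (gamma * L^2 + sum_e tension_e * l_e) / A,

so a compressed cell (A < A0, pure area term) has positive pressure.
Pressures are reported rescaled, p' = 1000 p, with the signed-log map
log10(p' + 1) / -log10(-p' + 1) for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, brentq

from .mesh import TissueState, MeshError

# perimeter of the regular hexagon of unit area
HEX_PERIMETER = 6.0 * np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))

try:  # optional JIT kernel for the hot energy/gradient evaluation
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _eg_kernel(coords, he_src, he_tgt, he_cell, e_src, e_tgt, e_lam,
                   K, A0, gamma, act, nc):
        nv = coords.shape[0]
        A = np.zeros(nc)
        L = np.zeros(nc)
        nhe = he_src.shape[0]
        for k in range(nhe):
            s, t = he_src[k], he_tgt[k]
            c = he_cell[k]
            A[c] += 0.5 * (coords[s, 0] * coords[t, 1] - coords[t, 0] * coords[s, 1])
            dx = coords[t, 0] - coords[s, 0]
            dy = coords[t, 1] - coords[s, 1]
            L[c] += np.sqrt(dx * dx + dy * dy)
        e = 0.0
        for c in range(nc):
            if act[c]:
                dA = A[c] - A0[c]
                e += 0.5 * K[c] * dA * dA + 0.5 * gamma[c] * L[c] * L[c]
        grad = np.zeros((nv, 2))
        for k in range(nhe):
            c = he_cell[k]
            if not act[c]:
                continue
            s, t = he_src[k], he_tgt[k]
            w = K[c] * (A[c] - A0[c])
            gL = gamma[c] * L[c]
            dx = coords[t, 0] - coords[s, 0]
            dy = coords[t, 1] - coords[s, 1]
            seg = np.sqrt(dx * dx + dy * dy)
            if seg == 0.0:
                seg = 1.0
            ux, uy = dx / seg, dy / seg
            grad[s, 0] += 0.5 * w * coords[t, 1] - gL * ux
            grad[s, 1] += -0.5 * w * coords[t, 0] - gL * uy
            grad[t, 0] += -0.5 * w * coords[s, 1] + gL * ux
            grad[t, 1] += 0.5 * w * coords[s, 0] + gL * uy
        ne = e_src.shape[0]
        for k in range(ne):
            lam = e_lam[k]
            if lam == 0.0:
                continue
            s, t = e_src[k], e_tgt[k]
            dx = coords[t, 0] - coords[s, 0]
            dy = coords[t, 1] - coords[s, 1]
            el = np.sqrt(dx * dx + dy * dy)
            e += lam * el
            if el == 0.0:
                el = 1.0
            tx, ty = lam * dx / el, lam * dy / el
            grad[s, 0] -= tx
            grad[s, 1] -= ty
            grad[t, 0] += tx
            grad[t, 1] += ty
        return e, grad

except Exception:  # pragma: no cover - numba missing or failing to JIT
    _eg_kernel = None


@dataclass
class MechanicsParams:
    """Mechanical and solver parameters (normalized units).

    The bulk line tension, contractility and preferred area default to
    the classic soft-matter parameter point for proliferating epithelia
    (tension 0.12, contractility 0.04, unit preferred area).  Boundary
    edges carry an elevated tension so that a compact, smooth outline
    is energetically favorable; with each edge counted once in the
    tension sum, ~0.45 is the largest confinement a ~50-cell tissue
    can sustain without boundary cells being crushed (the confining
    pressure scales as boundary_tension / tissue radius, while the
    bulk can resist only a finite pressure).  The default 0.40 keeps a
    stability margin across fixture realizations and already puts the
    outline circularity in its saturation regime.
    """

    line_tension: float = 0.12        # normalized bulk edge tension
    boundary_tension: float = 0.40    # tension override on boundary edges
    contractility: float = 0.04       # normalized perimeter contractility
    preferred_area: float = 1.0       # default A0 for newly created cells

    t1_threshold: float = 0.1         # edge length triggering a T1
    t1_post_factor: float = 1.05      # post-T1 edge length / threshold
    t2_area_threshold: float = 0.05   # apoptotic area for T2 removal
    t1_enabled: bool = True
    t2_enabled: bool = True
    t3_enabled: bool = True

    solver: str = "quasistatic"       # "quasistatic" | "viscous"
    viscosity: float = 1.0            # viscous solver only (arbitrary units)
    viscous_substeps: int = 100

    gtol: float = 1e-6                # gradient tolerance per relaxation round
    ftol: float = 1e-11               # relative energy-progress stop
    maxiter: int = 10000              # iteration cap per relaxation round
    max_rounds: int = 50              # minimize/topology interleaving cap


@dataclass
class EnergyBreakdown:
    total: float
    area_term: float
    tension_term: float
    contractility_term: float
    per_cell: dict[int, float]


@dataclass
class PressureField:
    """Per-cell pressure with the rescaled and signed-log views."""

    pressure: dict[int, float]          # p_c, energy / length^2

    @property
    def rescaled(self) -> dict[int, float]:
        return {cid: 1000.0 * p for cid, p in self.pressure.items()}

    @property
    def log_visual(self) -> dict[int, float]:
        out = {}
        for cid, p in self.pressure.items():
            pp = 1000.0 * p
            out[cid] = float(np.log10(pp + 1.0)) if pp >= 0 else float(-np.log10(-pp + 1.0))
        return out


@dataclass
class ConvergenceReport:
    converged: bool
    rounds: int
    iterations: int
    energy_initial: float
    energy_final: float
    grad_norm: float
    events: list = field(default_factory=list)


# ----------------------------------------------------------------------
# compiled geometry cache
# ----------------------------------------------------------------------
class GeometryCache:
    """Flat index arrays compiled from a :class:`TissueState`.

    Energy and gradient evaluations during minimization run on these
    arrays (all O(#edges) numpy operations); the cache is rebuilt only
    after a topology change.
    """

    def __init__(self, tissue: TissueState, params: MechanicsParams):
        self.tissue = tissue
        self.params = params
        used = tissue.used_vertices()
        self.vidx = used                                   # compiled -> global
        self.vmap = {int(v): i for i, v in enumerate(used)}  # global -> compiled
        self.nv = len(used)
        self.coords0 = tissue.vertices[used].copy()

        self.cell_ids = sorted(tissue.cells)
        cmap = {cid: i for i, cid in enumerate(self.cell_ids)}
        nc = len(self.cell_ids)
        self.K = np.array([tissue.cells[c].K for c in self.cell_ids])
        self.A0 = np.array([tissue.cells[c].A0 for c in self.cell_ids])
        self.gamma = np.array([tissue.cells[c].gamma for c in self.cell_ids])
        self.active = np.array([tissue.cells[c].active for c in self.cell_ids], dtype=bool)

        he_src, he_tgt, he_cell = [], [], []
        for cid in self.cell_ids:
            vs = tissue.cells[cid].vertices
            n = len(vs)
            ci = cmap[cid]
            for i in range(n):
                he_src.append(self.vmap[vs[i]])
                he_tgt.append(self.vmap[vs[(i + 1) % n]])
                he_cell.append(ci)
        self.he_src = np.array(he_src, dtype=int)
        self.he_tgt = np.array(he_tgt, dtype=int)
        self.he_cell = np.array(he_cell, dtype=int)

        # unique undirected edges with incident-cell count and activity
        emap = tissue.edge_cells()
        e_src, e_tgt, e_tension, e_on = [], [], [], []
        for (a, b), cids in emap.items():
            e_src.append(self.vmap[a])
            e_tgt.append(self.vmap[b])
            e_tension.append(
                params.boundary_tension if len(cids) == 1 else params.line_tension
            )
            e_on.append(any(tissue.cells[c].active for c in cids))
        self.e_src = np.array(e_src, dtype=int)
        self.e_tgt = np.array(e_tgt, dtype=int)
        self.e_tension = np.array(e_tension)
        self.e_on = np.array(e_on, dtype=bool)

        # vertices free to move: touch at least one active cell and no
        # inactive (differentiated) cell -- differentiated cells are
        # immotile, so every vertex of theirs stays pinned
        free = np.zeros(self.nv, dtype=bool)
        act_he = self.active[self.he_cell]
        free[self.he_src[act_he]] = True
        free[self.he_src[~act_he]] = False
        self.free = free
        self.nc = nc

    # -- raw terms -----------------------------------------------------
    def cell_geometry(self, coords: np.ndarray):
        """Per-cell signed areas and perimeters from compiled halfedges."""
        xs, ys = coords[self.he_src, 0], coords[self.he_src, 1]
        xt, yt = coords[self.he_tgt, 0], coords[self.he_tgt, 1]
        cross = xs * yt - xt * ys
        seg = np.hypot(xt - xs, yt - ys)
        A = 0.5 * np.bincount(self.he_cell, weights=cross, minlength=self.nc)
        L = np.bincount(self.he_cell, weights=seg, minlength=self.nc)
        return A, L

    def energy_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Total energy and its analytic gradient in one fused pass."""
        if _eg_kernel is not None:
            if not hasattr(self, "_kernel_args"):
                self._kernel_args = (
                    self.he_src, self.he_tgt, self.he_cell,
                    self.e_src, self.e_tgt,
                    (self.e_tension * self.e_on).astype(float),
                    self.K.astype(float), self.A0.astype(float),
                    self.gamma.astype(float), self.active,
                    self.nc,
                )
            e, g = _eg_kernel(np.ascontiguousarray(coords), *self._kernel_args)
            return float(e), g
        xs, ys = coords[self.he_src, 0], coords[self.he_src, 1]
        xt, yt = coords[self.he_tgt, 0], coords[self.he_tgt, 1]
        cross = xs * yt - xt * ys
        dx, dy = xt - xs, yt - ys
        seg = np.hypot(dx, dy)
        A = 0.5 * np.bincount(self.he_cell, weights=cross, minlength=self.nc)
        L = np.bincount(self.he_cell, weights=seg, minlength=self.nc)
        act = self.active
        dA = (A - self.A0) * act
        e_area = 0.5 * float((self.K * dA * dA).sum())
        e_contr = 0.5 * float((self.gamma * L * L * act).sum())

        # per-halfedge weights for the area and perimeter gradients
        w = self.K * (A - self.A0) * act
        whe = w[self.he_cell]
        seg_safe = np.where(seg == 0, 1.0, seg)
        gL = (self.gamma * L * act)[self.he_cell]
        ux, uy = dx / seg_safe, dy / seg_safe

        # edge tension on unique edges
        ed = coords[self.e_tgt] - coords[self.e_src]
        el = np.hypot(ed[:, 0], ed[:, 1])
        e_tension = float((self.e_tension * el * self.e_on).sum())
        el_safe = np.where(el == 0, 1.0, el)
        lam = self.e_tension * self.e_on
        tx, ty = lam * ed[:, 0] / el_safe, lam * ed[:, 1] / el_safe

        idx = np.concatenate([self.he_src, self.he_tgt, self.e_src, self.e_tgt])
        wx = np.concatenate([0.5 * whe * yt - gL * ux, -0.5 * whe * ys + gL * ux, -tx, tx])
        wy = np.concatenate([-0.5 * whe * xt - gL * uy, 0.5 * whe * xs + gL * uy, -ty, ty])
        grad = np.empty_like(coords)
        grad[:, 0] = np.bincount(idx, weights=wx, minlength=self.nv)
        grad[:, 1] = np.bincount(idx, weights=wy, minlength=self.nv)
        return e_area + e_tension + e_contr, grad

    def energy_terms(self, coords: np.ndarray):
        A, L = self.cell_geometry(coords)
        act = self.active
        e_area_c = 0.5 * self.K * (A - self.A0) ** 2 * act
        e_contr_c = 0.5 * self.gamma * L**2 * act
        d = coords[self.e_tgt] - coords[self.e_src]
        el = np.hypot(d[:, 0], d[:, 1])
        e_tension = float((self.e_tension * el * self.e_on).sum())
        return float(e_area_c.sum()), e_tension, float(e_contr_c.sum()), e_area_c, e_contr_c, A, L

    def energy(self, coords: np.ndarray) -> float:
        ea, et, ec, *_ = self.energy_terms(coords)
        return ea + et + ec

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        """Analytic dE/dr for every compiled vertex."""
        return self.energy_and_grad(coords)[1]


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------
def energy(tissue: TissueState, params: MechanicsParams) -> EnergyBreakdown:
    """Total energy with its per-term and per-cell breakdown."""
    cache = GeometryCache(tissue, params)
    ea, et, ec, e_area_c, e_contr_c, *_ = cache.energy_terms(cache.coords0)
    per_cell = {
        cid: float(e_area_c[i] + e_contr_c[i])
        for i, cid in enumerate(cache.cell_ids)
    }
    return EnergyBreakdown(
        total=ea + et + ec,
        area_term=ea,
        tension_term=et,
        contractility_term=ec,
        per_cell=per_cell,
    )


def forces(tissue: TissueState, params: MechanicsParams) -> dict[int, np.ndarray]:
    """Analytic force -dE/dr_i for every vertex (global indexing)."""
    cache = GeometryCache(tissue, params)
    g = cache.gradient(cache.coords0)
    return {int(v): -g[i] for i, v in enumerate(cache.vidx)}


def _minimize_round(tissue: TissueState, params: MechanicsParams):
    """One quasi-Newton minimization on fixed topology; edits coords in place."""
    cache = GeometryCache(tissue, params)
    free = cache.free
    x_fixed = cache.coords0.copy()

    def fun(x):
        coords = x_fixed.copy()
        coords[free] = x.reshape(-1, 2)
        e, g = cache.energy_and_grad(coords)
        return e, g[free].ravel()

    x0 = cache.coords0[free].ravel()
    e0 = cache.energy(cache.coords0)
    if x0.size == 0:
        return e0, e0, 0, 0.0, True
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": params.maxiter, "gtol": params.gtol, "ftol": params.ftol},
    )
    coords = x_fixed
    coords[free] = res.x.reshape(-1, 2)
    gnorm = float(np.abs(res.jac).max()) if res.jac is not None else np.nan
    # never accept an energy increase (line search pathologies)
    if res.fun <= e0:
        tissue.vertices[cache.vidx] = coords
        efin = float(res.fun)
    else:
        efin = e0
    return e0, efin, int(res.nit), gnorm, bool(res.success or gnorm < 10 * params.gtol)


def relax_quasistatic(
    tissue: TissueState,
    params: MechanicsParams,
    topology_enabled: bool = True,
    rng: np.random.Generator | None = None,
) -> ConvergenceReport:
    """Drive the tissue to the nearest local minimum of the energy.

    Minimization rounds are interleaved with scans for T1/T2/T3
    transitions until no transition fires (capped at
    ``params.max_rounds``).  Returns a convergence report with the
    transition events that fired; the tissue is modified in place.
    """
    from . import topology  # local import to avoid a cycle

    events = []
    e_init = None
    iters = 0
    rounds = 0
    converged = False
    gnorm = np.nan
    e_fin = np.nan
    for rounds in range(1, params.max_rounds + 1):
        e0, e_fin, nit, gnorm, ok = _minimize_round(tissue, params)
        if e_init is None:
            e_init = e0
        iters += nit
        converged = ok
        if not topology_enabled:
            break
        fired = topology.scan_and_fire(tissue, params)
        if not fired:
            break
        events.extend(fired)
    return ConvergenceReport(
        converged=converged,
        rounds=rounds,
        iterations=iters,
        energy_initial=float(e_init if e_init is not None else np.nan),
        energy_final=float(e_fin),
        grad_norm=float(gnorm),
        events=events,
    )


def relax_viscous(tissue: TissueState, params: MechanicsParams, dt: float) -> None:
    """Explicit overdamped update over one mechanical interval.

    The vertices take ``params.viscous_substeps`` equal force steps
    r <- r + (1/viscosity) * F * delta_t; by design there is no
    convergence criterion.  The tissue is modified in place.
    """
    if params.viscosity <= 0:
        raise ValueError("viscosity must be positive")
    nsub = params.viscous_substeps
    sub_dt = dt / nsub
    cache = GeometryCache(tissue, params)
    coords = cache.coords0.copy()
    free = cache.free
    for _ in range(nsub):
        g = cache.gradient(coords)
        coords[free] -= (sub_dt / params.viscosity) * g[free]
    tissue.vertices[cache.vidx] = coords


def cell_pressure(tissue: TissueState, params: MechanicsParams) -> PressureField:
    """Per-cell virial pressure (see module docstring for the closed form)."""
    cache = GeometryCache(tissue, params)
    A, L = cache.cell_geometry(cache.coords0)
    if np.any(A[cache.active] == 0):
        raise MeshError("zero-area cell in pressure computation")
    # tension of each cell's own edges (boundary override applies)
    emap = tissue.edge_cells()
    tension_sum = np.zeros(cache.nc)
    cmap = {cid: i for i, cid in enumerate(cache.cell_ids)}
    for (a, b), cids in emap.items():
        lam = params.boundary_tension if len(cids) == 1 else params.line_tension
        el = float(np.linalg.norm(tissue.vertices[a] - tissue.vertices[b]))
        for cid in cids:
            tension_sum[cmap[cid]] += lam * el
    p = np.where(
        cache.active & (A != 0),
        -2.0 * cache.K * (A - cache.A0) - (cache.gamma * L**2 + tension_sum) / np.where(A == 0, 1.0, A),
        0.0,
    )
    return PressureField(pressure={cid: float(p[cmap[cid]]) for cid in cache.cell_ids})


# ----------------------------------------------------------------------
# ground-state analysis: hexagonal vs soft network
# ----------------------------------------------------------------------
def _soft_margin(line_tension: float, contractility: float) -> float:
    """Preferred perimeter minus hexagonal perimeter at the ground state.

    Per cell of a periodic tiling the energy is
    e(a, p) = 1/2 (a-1)^2 + (tension/2) p + (contractility/2) p^2
    (each edge shared by two cells) subject to the packing constraint
    p >= HEX_PERIMETER * sqrt(a).  The network is *soft* when the
    unconstrained perimeter optimum p* = -tension / (2 contractility)
    is attainable, i.e. the constraint is slack at the minimizer: cells
    then have shape degeneracy and zero shear response.
    """
    if contractility <= 0:
        raise ValueError("contractility must be positive for the ground-state analysis")
    p_star = -line_tension / (2.0 * contractility)

    def cell_energy(a):
        p = HEX_PERIMETER * np.sqrt(a)
        return 0.5 * (a - 1.0) ** 2 + 0.5 * line_tension * p + 0.5 * contractility * p**2

    # constrained ground-state area along the hexagonal branch
    grid = np.linspace(0.05, 4.0, 400)
    a_star = grid[np.argmin([cell_energy(a) for a in grid])]
    res = minimize(cell_energy, x0=[a_star], bounds=[(1e-3, 10.0)])
    a_star = float(res.x[0])
    return p_star - HEX_PERIMETER * np.sqrt(a_star)


def soft_network_transition(
    contractility: float = 0.04,
    bracket: tuple[float, float] = (-1.0, 0.1),
) -> float:
    """Bulk line tension at the hexagonal-to-soft ground-state transition.

    Sweeps the normalized bulk tension at fixed contractility and
    locates, by root bisection on the shape-degeneracy margin, the
    tension below which the periodic ground state stops being the
    regular hexagonal network and becomes a degenerate soft network.
    """
    lo, hi = bracket
    return float(brentq(lambda lam: _soft_margin(lam, contractility), lo, hi, xtol=1e-6))
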