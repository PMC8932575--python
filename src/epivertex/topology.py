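"""Discrete rearrangement operators on the cell mesh.

* **T1** (neighbor exchange): an interior edge shorter than the T1
  threshold collapses and reopens perpendicular at a slightly longer
  length; the two cells that shared the edge lose a side, the two cells
  at its endpoints gain one.  The *inverse* T1 of a shrinking cell is
  the same operator seen from the side-losing cells; there is no
  separate code path.
* **T2** (cell removal): a triangular cell, or a cell below the
  apoptotic area threshold, is replaced by a single vertex joining its
  neighbors.  Sub-threshold cells with more than three sides are first
  shrunk by collapsing their shortest edges.
* **T3** (edge formation): a vertex of rank > 3 is split by inserting a
  new short edge between two of its incident cells, choosing the
  energy-minimizing split; when no split lowers the energy the vertex
  is left intact.
* **Division**: a new edge is cut along a uniformly random line through
  the cell centroid; daughters inherit the mother's concentration and
  mechanical parameters, and restart their cycle volume at V_d/2.

T1 firing is unconditional below the length threshold (energetic
favorability is enforced by the relaxation round that follows each
transition); ties between simultaneous candidates break on shortest
edge first, then lowest cell id, so that runs are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    Cell,
    MeshError,
    TissueState,
    cell_area,
    cell_centroid,
)


@dataclass
class TransitionEvent:
    kind: str                      # "T1" | "T2" | "T3" | "division"
    time: float
    cells: tuple[int, ...]         # participating cell ids
    trigger: float                 # edge length or area that fired it
    info: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _edge_len(tissue: TissueState, edge: tuple[int, int]) -> float:
    a, b = edge
    return float(np.linalg.norm(tissue.vertices[a] - tissue.vertices[b]))


def _directed_owner(tissue: TissueState, a: int, b: int) -> int | None:
    """Cell whose cycle traverses a -> b, or None."""
    for cid in tissue.vertex_cells().get(a, []):
        vs = tissue.cells[cid].vertices
        n = len(vs)
        for i in range(n):
            if vs[i] == a and vs[(i + 1) % n] == b:
                return cid
    return None


def _insert_before(cycle: list[int], anchor: int, new: int) -> None:
    cycle.insert(cycle.index(anchor), new)


def _remove_vertex(cycle: list[int], v: int) -> None:
    cycle.remove(v)


def _oversharing(tissue: TissueState, plans: dict[int, list[int]], removed: set[int] = frozenset()) -> bool:
    """True if applying ``plans`` (cell id -> new cycle) while deleting
    ``removed`` cells would leave any undirected edge with > 2 owners."""
    edge_count: dict[tuple[int, int], int] = {}
    for cid, cell in tissue.cells.items():
        if cid in removed:
            continue
        vs = plans.get(cid, cell.vertices)
        for k in range(len(vs)):
            u, v = vs[k], vs[(k + 1) % len(vs)]
            key = (u, v) if u < v else (v, u)
            edge_count[key] = edge_count.get(key, 0) + 1
            if edge_count[key] > 2:
                return True
    return False


# ----------------------------------------------------------------------
# T1 neighbor exchange
# ----------------------------------------------------------------------
def t1_eligible(tissue: TissueState, edge: tuple[int, int]) -> bool:
    """True if ``edge`` can undergo a T1 (four distinct incident cells,
    interior rank-3 endpoints, side-losing cells keep >= 3 sides)."""
    emap = tissue.edge_cells()
    cids = emap.get(tuple(sorted(edge)))
    if cids is None or len(cids) != 2:
        return False
    P, Q = cids
    if len(tissue.cells[P].vertices) < 4 or len(tissue.cells[Q].vertices) < 4:
        return False
    a, b = edge
    vmap = tissue.vertex_cells()
    at_a = set(vmap.get(a, []))
    at_b = set(vmap.get(b, []))
    if len(at_a) != 3 or len(at_b) != 3:
        return False
    third_a = at_a - {P, Q}
    third_b = at_b - {P, Q}
    if len(third_a) != 1 or len(third_b) != 1:
        return False
    R, S = third_a.pop(), third_b.pop()
    if R == S:
        return False
    # avoid creating a doubled edge between cells already adjacent
    if S in tissue.neighbors()[R]:
        return False
    return True


def t1_transition(
    tissue: TissueState, edge: tuple[int, int], post_length: float
) -> TransitionEvent:
    """Collapse ``edge`` and reopen it perpendicular at ``post_length``.

    The two cells that shared the edge each lose one side, the two
    cells at its endpoints each gain one; the cell count is unchanged.
    """
    a, b = edge
    if not t1_eligible(tissue, edge):
        raise MeshError(f"edge {edge} is not T1-eligible")
    P = _directed_owner(tissue, a, b)
    Q = _directed_owner(tissue, b, a)
    vmap = tissue.vertex_cells()
    R = next(c for c in vmap[a] if c not in (P, Q))
    S = next(c for c in vmap[b] if c not in (P, Q))
    trigger = _edge_len(tissue, edge)

    _remove_vertex(tissue.cells[P].vertices, b)
    _remove_vertex(tissue.cells[Q].vertices, a)
    _insert_before(tissue.cells[R].vertices, a, b)   # R: ..., b, a, ...
    _insert_before(tissue.cells[S].vertices, b, a)   # S: ..., a, b, ...

    ra, rb = tissue.vertices[a], tissue.vertices[b]
    m = 0.5 * (ra + rb)
    d = rb - ra
    nd = np.linalg.norm(d)
    d = d / nd if nd > 0 else np.array([1.0, 0.0])
    n_left = np.array([-d[1], d[0]])          # P lies left of a->b
    tissue.vertices[a] = m + 0.5 * post_length * n_left
    tissue.vertices[b] = m - 0.5 * post_length * n_left
    tissue.invalidate()
    return TransitionEvent("T1", tissue.time, (P, Q, R, S), trigger)


def t1_candidates(tissue: TissueState, threshold: float) -> list[tuple[float, tuple[int, int]]]:
    """Interior edges below the T1 length threshold, shortest first."""
    out = []
    for e, cids in tissue.edge_cells().items():
        if len(cids) != 2:
            continue
        ln = _edge_len(tissue, e)
        if ln < threshold and t1_eligible(tissue, e):
            out.append((ln, e))
    out.sort(key=lambda it: (it[0], it[1]))
    return out


# ----------------------------------------------------------------------
# edge collapse (shared by the T2 shrink path)
# ----------------------------------------------------------------------
def collapse_edge(tissue: TissueState, edge: tuple[int, int]) -> bool:
    """Merge the endpoints of ``edge`` into one vertex at the midpoint.

    Every cell whose cycle contains the edge loses a side.  Returns
    False (no edit) if any such cell is a triangle or if a cell
    contains both endpoints non-adjacently (pinch)."""
    a, b = edge
    vmap = tissue.vertex_cells()
    affected = set(vmap.get(a, [])) | set(vmap.get(b, []))
    plans = {}
    for cid in affected:
        vs = tissue.cells[cid].vertices
        has_a, has_b = a in vs, b in vs
        if has_a and has_b:
            n = len(vs)
            ia, ib = vs.index(a), vs.index(b)
            if (ia - ib) % n not in (1, n - 1):
                return False                      # pinch
            if n <= 3:
                return False                      # would create a 2-gon
            plans[cid] = [v for v in vs if v != b]
        elif has_b:
            plans[cid] = [a if v == b else v for v in vs]
    if _oversharing(tissue, plans):
        return False
    mid = 0.5 * (tissue.vertices[a] + tissue.vertices[b])
    for cid, newvs in plans.items():
        tissue.cells[cid].vertices = newvs
    tissue.vertices[a] = mid
    tissue.invalidate()
    return True


# ----------------------------------------------------------------------
# T2 removal
# ----------------------------------------------------------------------
def t2_remove(tissue: TissueState, cid: int) -> TransitionEvent:
    """Remove a triangular cell, replacing it by a single vertex."""
    cell = tissue.cells[cid]
    if len(cell.vertices) != 3:
        raise MeshError(f"T2 removal requires a triangle, cell {cid} has {len(cell.vertices)} sides")
    a, b, c = cell.vertices
    area = cell_area(tissue, cid)
    centroid = tissue.vertices[np.array([a, b, c])].mean(axis=0)
    neighbors = sorted(
        set().union(*[tissue.vertex_cells().get(v, []) for v in (a, b, c)]) - {cid}
    )
    # plan all neighbor repairs before committing anything
    plans = {}
    for nid in neighbors:
        vs = [a if v in (b, c) else v for v in tissue.cells[nid].vertices]
        dedup = []
        for v in vs:
            if not dedup or dedup[-1] != v:
                dedup.append(v)
        if len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if len(dedup) < 3:
            raise MeshError(f"T2 removal of cell {cid} degenerates neighbor {nid}")
        if len(set(dedup)) != len(dedup):
            raise MeshError(f"T2 removal of cell {cid} pinches neighbor {nid}")
        plans[nid] = dedup
    if _oversharing(tissue, plans, removed={cid}):
        raise MeshError(f"T2 removal of cell {cid} would over-share an edge")
    del tissue.cells[cid]
    for nid, dedup in plans.items():
        tissue.cells[nid].vertices = dedup
    tissue.vertices[a] = centroid
    tissue.invalidate()
    return TransitionEvent("T2", tissue.time, (cid,), area, {"neighbors": neighbors})


def t2_shrink_and_remove(tissue: TissueState, cid: int) -> TransitionEvent | None:
    """Shrink a sub-threshold cell to a triangle by collapsing its
    shortest edges, then remove it.  Returns None if blocked."""
    guard = 0
    while len(tissue.cells[cid].vertices) > 3 and guard < 20:
        guard += 1
        vs = tissue.cells[cid].vertices
        n = len(vs)
        edges = sorted(
            ((_edge_len(tissue, (vs[i], vs[(i + 1) % n])), (vs[i], vs[(i + 1) % n])) for i in range(n)),
            key=lambda it: it[0],
        )
        done = False
        for _, e in edges:
            if collapse_edge(tissue, e):
                done = True
                break
        if not done:
            return None
    if len(tissue.cells[cid].vertices) != 3:
        return None
    return t2_remove(tissue, cid)


def t2_candidates(tissue: TissueState, area_threshold: float) -> list[int]:
    """Cells due for T2: below the apoptotic area, or triangular and
    small (a large triangle, e.g. from boundary construction, is a
    perfectly viable cell and is kept)."""
    out = []
    for cid, cell in tissue.cells.items():
        if not cell.active:
            continue
        a = cell_area(tissue, cid)
        if a < area_threshold or (len(cell.vertices) == 3 and a < 4.0 * area_threshold):
            out.append(cid)
    return sorted(out)


# ----------------------------------------------------------------------
# T3 vertex split
# ----------------------------------------------------------------------
def _fan_order(tissue: TissueState, v: int) -> tuple[list[int], list[int]] | None:
    """Cyclic order of cells and spoke vertices around an interior
    vertex: cell C_i lies between spokes u_{i-1} and u_i, and traverses
    ..., u_{i-1}, v, u_i, ... in its cycle.  None for boundary vertices."""
    cells_at = tissue.vertex_cells().get(v, [])
    prev_next = {}
    for cid in cells_at:
        vs = tissue.cells[cid].vertices
        i = vs.index(v)
        prev_next[cid] = (vs[i - 1], vs[(i + 1) % len(vs)])
    by_prev = {pn[0]: cid for cid, pn in prev_next.items()}
    start = cells_at[0]
    order = [start]
    spokes = []
    cur = start
    for _ in range(len(cells_at)):
        nxt_spoke = prev_next[cur][1]
        spokes.append(nxt_spoke)
        nxt_cell = by_prev.get(nxt_spoke)
        if nxt_cell is None:
            return None                       # boundary fan, not closed
        if nxt_cell == start:
            break
        order.append(nxt_cell)
        cur = nxt_cell
    if len(order) != len(cells_at) or len(spokes) != len(cells_at):
        return None
    return order, spokes


def t3_resolve(
    tissue: TissueState,
    v: int,
    post_length: float,
    energy_fn,
) -> TransitionEvent | None:
    """Split a rank > 3 vertex by inserting a short edge, if a split
    lowers the energy.  ``energy_fn(tissue) -> float`` scores trial
    configurations.  Ties between equal-energy splits break on the
    lowest participating cell id."""
    fan = _fan_order(tissue, v)
    if fan is None:
        return None
    cells_cyc, spokes = fan
    r = len(cells_cyc)
    if r <= 3:
        return None
    e_before = energy_fn(tissue)
    best = None
    for k in range(r):
        trial = tissue.copy()
        C = cells_cyc[k:] + cells_cyc[:k]     # rotate so C[0] splits off
        v2 = len(trial.vertices)
        trial.vertices = np.vstack([trial.vertices, trial.vertices[v][None, :]])
        # C[0] keeps v; C[2..r-2] take v2; C[1] gets v,v2; C[r-1] gets v2,v
        for cid in C[2:-1]:
            vs = trial.cells[cid].vertices
            trial.cells[cid].vertices = [v2 if x == v else x for x in vs]
        vs1 = trial.cells[C[1]].vertices
        i1 = vs1.index(v)
        trial.cells[C[1]].vertices = vs1[: i1 + 1] + [v2] + vs1[i1 + 1 :]
        vsr = trial.cells[C[-1]].vertices
        ir = vsr.index(v)
        trial.cells[C[-1]].vertices = vsr[:ir] + [v2] + vsr[ir:]
        # displace along the line joining the two separated cells
        try:
            g0 = cell_centroid(trial, C[0])
            others = [cell_centroid(trial, cid) for cid in C[2:-1]]
            g2 = np.mean(others, axis=0) if others else 2 * trial.vertices[v] - g0
            d = g0 - g2
            nd = np.linalg.norm(d)
            d = d / nd if nd > 0 else np.array([1.0, 0.0])
            trial.vertices[v] = tissue.vertices[v] + 0.5 * post_length * d
            trial.vertices[v2] = tissue.vertices[v] - 0.5 * post_length * d
            trial.invalidate()
            if any(cell_area(trial, cid) <= 0 for cid in C):
                continue
            e_trial = energy_fn(trial)
        except MeshError:
            continue
        key = (round(e_trial, 10), min(C[1], C[-1]))
        if best is None or key < best[0]:
            best = (key, e_trial, trial, (C[1], C[-1]))
    if best is None or best[1] >= e_before - 1e-12:
        return None
    _, _, trial, pair = best
    tissue.vertices = trial.vertices
    tissue.cells = trial.cells
    tissue.invalidate()
    return TransitionEvent("T3", tissue.time, pair, float(r))


def high_rank_vertices(tissue: TissueState) -> list[int]:
    return sorted(v for v, cs in tissue.vertex_cells().items() if len(cs) > 3)


# ----------------------------------------------------------------------
# cell division
# ----------------------------------------------------------------------
def _line_polygon_cuts(coords: np.ndarray, point: np.ndarray, direction: np.ndarray):
    """Intersections of an infinite line with the polygon boundary.

    Returns a list of (edge_index, fraction_along_edge, xy)."""
    n = len(coords)
    cuts = []
    d = direction
    for i in range(n):
        p, q = coords[i], coords[(i + 1) % n]
        e = q - p
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-14:
            continue
        w = p - point
        s = -(d[0] * w[1] - d[1] * w[0]) / denom      # fraction along edge
        if -1e-9 <= s < 1.0 - 1e-9:
            s = min(max(s, 0.0), 1.0)
            cuts.append((i, s, p + s * e))
    return cuts


def divide_cell(
    tissue: TissueState,
    cid: int,
    rng: np.random.Generator,
    vd: float = 1.0,
    max_retries: int = 20,
) -> TransitionEvent:
    """Divide a cell along a random line through its centroid.

    Both daughters inherit the mother's concentration, region and
    mechanical parameters; each starts its cycle at ``vd / 2``.  The
    combined daughter area equals the mother area exactly (before any
    relaxation)."""
    cell = tissue.cells[cid]
    coords = tissue.vertices[np.asarray(cell.vertices, dtype=int)]
    g = cell_centroid(tissue, cid)
    vs = cell.vertices
    n = len(vs)
    for _ in range(max_retries):
        theta = rng.uniform(0.0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        cuts = _line_polygon_cuts(coords, g, d)
        if len(cuts) != 2:
            continue
        (i, si, p1), (j, sj, p2) = cuts
        if i == j:
            continue
        if i > j:
            (i, si, p1), (j, sj, p2) = (j, sj, p2), (i, si, p1)
        # avoid cutting exactly through an existing vertex
        if min(si, 1 - si) < 1e-6 or min(sj, 1 - sj) < 1e-6:
            continue
        w1 = len(tissue.vertices)
        w2 = w1 + 1
        tissue.vertices = np.vstack([tissue.vertices, p1[None, :], p2[None, :]])
        d1_cycle = [w1] + vs[i + 1 : j + 1] + [w2]
        d2_cycle = [w2] + vs[j + 1 :] + vs[: i + 1] + [w1]
        if len(d1_cycle) < 3 or len(d2_cycle) < 3:
            tissue.vertices = tissue.vertices[:-2]
            continue
        # insert the cut vertices into the neighbors sharing the cut edges
        for (eidx, w) in ((i, w1), (j, w2)):
            a, b = vs[eidx], vs[(eidx + 1) % n]
            nb = _directed_owner(tissue, b, a)
            if nb is not None and nb != cid:
                nvs = tissue.cells[nb].vertices
                k = nvs.index(b)
                if nvs[(k + 1) % len(nvs)] != a:
                    # b->a not adjacent means a wrap position; find exact spot
                    for k2 in range(len(nvs)):
                        if nvs[k2] == b and nvs[(k2 + 1) % len(nvs)] == a:
                            k = k2
                            break
                tissue.cells[nb].vertices = nvs[: k + 1] + [w] + nvs[k + 1 :]
        did1, did2 = tissue.new_cell_id(), tissue.new_cell_id()
        for did, cyc in ((did1, d1_cycle), (did2, d2_cycle)):
            tissue.cells[did] = Cell(
                vertices=cyc,
                A0=cell.A0,
                K=cell.K,
                gamma=cell.gamma,
                V=vd / 2.0,
                c=cell.c,
                region=cell.region,
                active=cell.active,
                A0_ref=cell.A0_ref,
            )
        del tissue.cells[cid]
        tissue.invalidate()
        return TransitionEvent(
            "division", tissue.time, (cid, did1, did2), float(theta),
            {"daughters": (did1, did2)},
        )
    raise MeshError(f"division of cell {cid} failed after {max_retries} orientations")


# ----------------------------------------------------------------------
# transition scan used between minimization rounds
# ----------------------------------------------------------------------
def scan_and_fire(tissue: TissueState, params) -> list[TransitionEvent]:
    """Fire due transitions once: all T2 removals, then the single
    shortest T1 candidate, then T3 resolution of high-rank vertices.
    Returns the events that fired (empty when the topology is stable)."""
    from .mechanics import energy as _energy  # local import avoids a cycle

    events: list[TransitionEvent] = []
    if params.t2_enabled:
        guard = 0
        blocked: set[int] = set()
        while guard < 100:
            guard += 1
            cands = [c for c in t2_candidates(tissue, params.t2_area_threshold) if c not in blocked]
            if not cands:
                break
            cid = cands[0]
            try:
                if len(tissue.cells[cid].vertices) == 3:
                    ev = t2_remove(tissue, cid)
                else:
                    ev = t2_shrink_and_remove(tissue, cid)
            except MeshError:
                ev = None
            if ev is None:
                blocked.add(cid)
                continue
            events.append(ev)
    if params.t1_enabled:
        cands = t1_candidates(tissue, params.t1_threshold)
        if cands:
            _, e = cands[0]
            events.append(
                t1_transition(tissue, e, params.t1_post_factor * params.t1_threshold)
            )
    if params.t3_enabled:
        for v in high_rank_vertices(tissue):
            ev = t3_resolve(
                tissue,
                v,
                params.t1_post_factor * params.t1_threshold,
                lambda t: _energy(t, params).total,
            )
            if ev is not None:
                events.append(ev)
    return events
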