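"""Planar polygonal cell-mesh data structure for 2D vertex models.

A confluent epithelium is represented as a tiling of simple polygons
(cells) over a shared pool of vertices.  Every cell stores its vertex
cycle in counterclockwise (CCW) order, so each interior edge appears in
exactly two cells with opposite direction and each boundary edge in
exactly one.  On top of the geometry each cell carries its physiology:
preferred area ``A0``, area elasticity ``K``, perimeter contractility
``gamma``, cell-cycle volume ``V``, morphogen concentration ``c``, a
region label and an ``active`` flag (differentiated cells keep their
geometry but are dropped from the mechanical energy).

Coordinates are dimensionless simulation units; conversion to microns
and hours is handled by the calibration layer in
:mod:`epivertex.scenarios`.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

SNAPSHOT_VERSION = "1"

#: Region labels.  ``posterior`` means posterior-undifferentiated.
REGIONS = ("anterior", "MF", "posterior", "differentiated")


class MeshError(ValueError):
    """Structural problem with the cell mesh (degenerate cell, broken
    edge sharing, disconnected boundary, ...)."""


class SnapshotError(ValueError):
    """Malformed or unsupported snapshot file."""


@dataclass
class Cell:
    """One polygonal cell and its physiological state."""

    vertices: list[int]            # CCW vertex cycle
    A0: float = 1.0                # preferred area (current, may be constricted)
    K: float = 1.0                 # area elasticity
    gamma: float = 0.04            # perimeter contractility (normalized)
    V: float = 0.5                 # cell-cycle volume in [V_d/2, V_d)
    c: float = 0.0                 # morphogen concentration
    region: str = "anterior"
    active: bool = True
    A0_ref: float | None = None    # unconstricted preferred area
    mf_exit_time: float | None = None

    def __post_init__(self) -> None:
        if self.A0_ref is None:
            self.A0_ref = self.A0


@dataclass
class TissueState:
    """Cell mesh plus per-cell physiology and the simulation clock."""

    vertices: np.ndarray                 # (Nv, 2) float64
    cells: dict[int, Cell]
    time: float = 0.0
    meta: dict = field(default_factory=dict)
    _next_cell_id: int = 0
    _version: int = 0                    # bumped on any topology change
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.cells and self._next_cell_id <= max(self.cells):
            self._next_cell_id = max(self.cells) + 1

    # ------------------------------------------------------------------
    # bookkeeping
    # ------------------------------------------------------------------
    def new_cell_id(self) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        return cid

    def invalidate(self) -> None:
        """Mark derived topology caches stale after a topology edit."""
        self._version += 1
        self._cache.clear()

    def copy(self) -> "TissueState":
        t = TissueState(
            vertices=self.vertices.copy(),
            cells={cid: _copy.copy(cell) for cid, cell in self.cells.items()},
            time=self.time,
            meta=dict(self.meta),
            _next_cell_id=self._next_cell_id,
        )
        for cell in t.cells.values():
            cell.vertices = list(cell.vertices)
        return t

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def used_vertices(self) -> np.ndarray:
        """Indices of vertices referenced by at least one cell."""
        used = set()
        for cell in self.cells.values():
            used.update(cell.vertices)
        return np.array(sorted(used), dtype=int)

    # ------------------------------------------------------------------
    # derived topology (cached)
    # ------------------------------------------------------------------
    def edge_cells(self) -> dict[tuple[int, int], list[int]]:
        """Map undirected edge (min_v, max_v) -> ids of incident cells."""
        cached = self._cache.get("edge_cells")
        if cached is not None:
            return cached
        emap: dict[tuple[int, int], list[int]] = {}
        for cid, cell in self.cells.items():
            vs = cell.vertices
            n = len(vs)
            for i in range(n):
                a, b = vs[i], vs[(i + 1) % n]
                key = (a, b) if a < b else (b, a)
                emap.setdefault(key, []).append(cid)
        self._cache["edge_cells"] = emap
        return emap

    def vertex_cells(self) -> dict[int, list[int]]:
        """Map vertex index -> ids of cells whose cycle contains it."""
        cached = self._cache.get("vertex_cells")
        if cached is not None:
            return cached
        vmap: dict[int, list[int]] = {}
        for cid, cell in self.cells.items():
            for v in cell.vertices:
                vmap.setdefault(v, []).append(cid)
        self._cache["vertex_cells"] = vmap
        return vmap

    def neighbors(self) -> dict[int, set[int]]:
        """Cell adjacency graph from shared edges."""
        cached = self._cache.get("neighbors")
        if cached is not None:
            return cached
        nmap: dict[int, set[int]] = {cid: set() for cid in self.cells}
        for cids in self.edge_cells().values():
            if len(cids) == 2:
                a, b = cids
                nmap[a].add(b)
                nmap[b].add(a)
        self._cache["neighbors"] = nmap
        return nmap


# ----------------------------------------------------------------------
# geometric queries
# ----------------------------------------------------------------------
def _cycle_coords(tissue: TissueState, cell: int | Cell) -> np.ndarray:
    c = tissue.cells[cell] if not isinstance(cell, Cell) else cell
    if len(c.vertices) < 3:
        raise MeshError(f"degenerate cell with {len(c.vertices)} vertices")
    return tissue.vertices[np.asarray(c.vertices, dtype=int)]


def polygon_area(coords: np.ndarray) -> float:
    """Signed shoelace area of an ordered vertex cycle (CCW positive)."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_perimeter(coords: np.ndarray) -> float:
    d = np.roll(coords, -1, axis=0) - coords
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(coords: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon."""
    x, y = coords[:, 0], coords[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if a == 0.0:
        raise MeshError("zero-area cell has no centroid")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def cell_area(tissue: TissueState, cell: int) -> float:
    """Shoelace area of a cell; positive under the CCW convention."""
    return polygon_area(_cycle_coords(tissue, cell))


def cell_perimeter(tissue: TissueState, cell: int) -> float:
    return polygon_perimeter(_cycle_coords(tissue, cell))


def cell_centroid(tissue: TissueState, cell: int, mode: str = "area") -> np.ndarray:
    """Cell centroid.

    ``mode='area'`` (default) is the polygon area centroid, robust for
    irregular cells; ``mode='vertex'`` is the plain vertex mean.
    """
    coords = _cycle_coords(tissue, cell)
    if mode == "vertex":
        return coords.mean(axis=0)
    if mode == "area":
        return polygon_centroid(coords)
    raise ValueError(f"unknown centroid mode {mode!r}")


def cell_centroid_safe(tissue: TissueState, cell: int) -> np.ndarray:
    """Area centroid with a vertex-mean fallback for transiently
    degenerate (zero-area) cells; observation helper, never used for
    mechanics."""
    try:
        return cell_centroid(tissue, cell)
    except MeshError:
        return _cycle_coords(tissue, cell).mean(axis=0)


def cell_areas(tissue: TissueState) -> dict[int, float]:
    return {cid: cell_area(tissue, cid) for cid in tissue.cells}


def boundary_edges(tissue: TissueState) -> set[tuple[int, int]]:
    """Undirected edges incident to exactly one cell.

    Returns the empty set for periodic (boundary-free) meshes.  Raises
    :class:`MeshError` if the boundary edges do not form closed loops or
    form more than one loop (disconnected tissue or interior hole).
    """
    emap = tissue.edge_cells()
    bedges = {e for e, cids in emap.items() if len(cids) == 1}
    if not bedges:
        return bedges
    # check: boundary forms exactly one closed loop
    adj: dict[int, list[int]] = {}
    for a, b in bedges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    if any(len(vs) != 2 for vs in adj.values()):
        raise MeshError("boundary is not a simple closed loop")
    start = next(iter(adj))
    seen = {start}
    prev, cur = None, start
    while True:
        nxt = [v for v in adj[cur] if v != prev]
        # in a closed loop of >2 vertices exactly one way forward
        step = nxt[0] if nxt else adj[cur][0]
        prev, cur = cur, step
        if cur == start:
            break
        if cur in seen:
            raise MeshError("boundary loop revisits a vertex")
        seen.add(cur)
    if seen != set(adj):
        raise MeshError("boundary edges form more than one loop")
    return bedges


def boundary_loop(tissue: TissueState) -> list[int]:
    """Boundary vertices in cyclic order (arbitrary starting point)."""
    bedges = boundary_edges(tissue)
    if not bedges:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in bedges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = next(iter(adj))
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [v for v in adj[cur] if v != prev]
        step = nxt[0] if nxt else adj[cur][0]
        prev, cur = cur, step
        if cur == start:
            break
        loop.append(cur)
    return loop


def tissue_boundary_polygon(tissue: TissueState) -> np.ndarray:
    """Coordinates of the outer boundary loop (CCW)."""
    loop = boundary_loop(tissue)
    coords = tissue.vertices[np.asarray(loop, dtype=int)]
    if polygon_area(coords) < 0:
        coords = coords[::-1]
    return coords


def validate(tissue: TissueState, geometric: bool = True) -> None:
    """Check the structural invariants of the mesh.

    Raises :class:`MeshError` on the first violation.  ``geometric=False``
    skips coordinate-based checks (used for topologically periodic
    fixture patches whose wrap-around edges have no consistent
    embedding in the plane).
    """
    emap = tissue.edge_cells()
    for e, cids in emap.items():
        if len(cids) > 2:
            raise MeshError(f"edge {e} shared by {len(cids)} cells")
        if len(cids) == 2:
            a, b = cids
            # opposite direction in the two cycles
            if _edge_direction(tissue.cells[a], e) == _edge_direction(tissue.cells[b], e):
                raise MeshError(f"edge {e} has same direction in cells {a} and {b}")
    for cid, cell in tissue.cells.items():
        if len(cell.vertices) < 3:
            raise MeshError(f"cell {cid} has fewer than 3 vertices")
        if len(set(cell.vertices)) != len(cell.vertices):
            raise MeshError(f"cell {cid} repeats a vertex")
        if cell.region not in REGIONS:
            raise MeshError(f"cell {cid} has unknown region {cell.region!r}")
    if geometric:
        for cid in tissue.cells:
            if cell_area(tissue, cid) <= 0:
                raise MeshError(f"cell {cid} has non-positive signed area")
        boundary_edges(tissue)  # raises if not a single closed loop


def _edge_direction(cell: Cell, edge: tuple[int, int]) -> bool:
    """True if the cycle traverses ``edge`` from min-vertex to max-vertex."""
    vs = cell.vertices
    n = len(vs)
    a, b = edge
    for i in range(n):
        u, v = vs[i], vs[(i + 1) % n]
        if (u, v) == (a, b):
            return True
        if (u, v) == (b, a):
            return False
    raise MeshError(f"edge {edge} not in cell cycle")


def compact(tissue: TissueState) -> TissueState:
    """Drop unused vertex slots and renumber; returns a new tissue."""
    used = tissue.used_vertices()
    remap = {int(v): i for i, v in enumerate(used)}
    t = tissue.copy()
    t.vertices = tissue.vertices[used]
    for cell in t.cells.values():
        cell.vertices = [remap[v] for v in cell.vertices]
    t.invalidate()
    return t


# ----------------------------------------------------------------------
# snapshot I/O (versioned JSON container)
# ----------------------------------------------------------------------
def write_snapshot(tissue: TissueState, path) -> None:
    """Write a lossless JSON snapshot of the tissue state.

    Floats are serialized via ``repr`` round-trip (shortest exact
    decimal), so ``read(write(T))`` reproduces coordinates bit-exactly.
    """
    edges = []
    for (a, b), cids in sorted(tissue.edge_cells().items()):
        for cid in cids:
            edges.append([int(a), int(b), int(cid)])
    doc = {
        "meta": {
            "time": tissue.time,
            "units": tissue.meta.get("units", "simulation"),
            "version": SNAPSHOT_VERSION,
            **{k: v for k, v in tissue.meta.items() if k != "units"},
        },
        "vertices": [[float(x), float(y)] for x, y in tissue.vertices],
        "edges": edges,
        "cells": {
            str(cid): {
                "vertex_cycle": [int(v) for v in cell.vertices],
                "A0": cell.A0,
                "A0_ref": cell.A0_ref,
                "K": cell.K,
                "gamma": cell.gamma,
                "V": cell.V,
                "c": cell.c,
                "region": cell.region,
                "active": cell.active,
                "mf_exit_time": cell.mf_exit_time,
            }
            for cid, cell in tissue.cells.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_snapshot(path) -> TissueState:
    """Read a snapshot written by :func:`write_snapshot`."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SnapshotError(f"not valid JSON: {exc}") from exc
    meta = doc.get("meta", {})
    version = str(meta.get("version"))
    if version != SNAPSHOT_VERSION:
        raise SnapshotError(
            f"unsupported snapshot version {version!r} (expected {SNAPSHOT_VERSION!r})"
        )
    vertices = np.asarray(doc["vertices"], dtype=float)
    nv = len(vertices)
    cells: dict[int, Cell] = {}
    for key, rec in doc["cells"].items():
        cyc = rec["vertex_cycle"]
        for v in cyc:
            if not (0 <= v < nv):
                raise SnapshotError(f"cell {key}: vertex {v} out of range (n={nv})")
        cells[int(key)] = Cell(
            vertices=list(cyc),
            A0=rec["A0"],
            K=rec["K"],
            gamma=rec["gamma"],
            V=rec["V"],
            c=rec["c"],
            region=rec["region"],
            active=rec["active"],
            A0_ref=rec.get("A0_ref", rec["A0"]),
            mf_exit_time=rec.get("mf_exit_time"),
        )
    for e in doc.get("edges", []):
        a, b, cid = e
        if not (0 <= a < nv and 0 <= b < nv):
            raise SnapshotError(f"edge record {e} references a missing vertex")
        if cid not in cells:
            raise SnapshotError(f"edge record {e} references a missing cell")
    extra = {k: v for k, v in meta.items() if k not in ("time", "version")}
    return TissueState(vertices=vertices, cells=cells, time=float(meta.get("time", 0.0)), meta=extra)
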