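"""Global tile positioning and mosaic assembly.

The constraint graph is an overdetermined system: each active constraint
contributes the two score-weighted equations

    s_ij (x_j - x_i) = s_ij dx_ij      s_ij (y_j - y_i) = s_ij dy_ij

Minimising the weighted mean absolute error of this system is cast as a
linear program with two nonnegative slack variables per equation
(``t - u`` splits the signed residual), whose objective is the slack sum.
A weighted-least-squares (MSE) solver on the same rows and a maximum-score
spanning-tree solver are provided as alternatives.  The x and y systems are
independent and are solved separately; the reported objective is their sum.

Positions are gauge-free (adding a common translation changes nothing), so
one anchor tile — the first tile of the first cycle by default — is pinned
to (0, 0) to make solutions unique and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.sparse.linalg import lsqr

from .registration import ConstraintGraph
from .tiles import TileCollection

__all__ = [
    "GlobalLayout",
    "StitchedImage",
    "solve_positions",
    "integerize_positions",
    "merge_tiles",
    "mae_objective",
]


@dataclass
class GlobalLayout:
    """Solved global tile positions (float stage, then integer stage)."""

    positions: dict[int, np.ndarray]  # tile id -> float (x, y)
    anchor: int
    method: str
    objective: float
    graph: ConstraintGraph | None = None
    positions_int: dict[int, np.ndarray] = field(default_factory=dict)
    objective_int: float | None = None
    int_method: str | None = None


@dataclass
class StitchedImage:
    """Per-cycle stitched rasters embedded in one common coordinate frame.

    ``data`` has shape (N_cycles, N_channels, H, W); ``origin`` is the
    ``(x, y)`` of pixel (0, 0) in layout coordinates.  ``coverage`` counts
    contributing tiles per (cycle, pixel); pixels with zero contributors are
    empty, not zero-intensity — consult the mask, not the value.
    """

    data: np.ndarray
    origin: tuple[int, int]
    coverage: np.ndarray
    fiducial_channel: int = 0

    @property
    def n_cycles(self) -> int:
        return self.data.shape[0]

    def mask(self, cycle: int) -> np.ndarray:
        return self.coverage[cycle] > 0

    def fiducial(self, cycle: int) -> np.ndarray:
        return self.data[cycle, self.fiducial_channel]


def _edges(graph: ConstraintGraph):
    """Active edges as (i, j, dx, dy, weight) with floored positive weights."""
    floor = graph.weight_floor
    return [
        (c.i, c.j, c.dx_refined, c.dy_refined, c.weight(floor))
        for c in graph.active
    ]


def mae_objective(graph: ConstraintGraph, positions: dict[int, np.ndarray]) -> float:
    """Sum of score-weighted absolute residuals at the given positions."""
    total = 0.0
    for i, j, dx, dy, w in _edges(graph):
        rx = positions[j][0] - positions[i][0] - dx
        ry = positions[j][1] - positions[i][1] - dy
        total += w * (abs(rx) + abs(ry))
    return total


def _components(node_ids, edges):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(node_ids)
    g.add_edges_from((i, j) for i, j, *_ in edges)
    return [sorted(c) for c in nx.connected_components(g)]


def _solve_axis_mae(nodes, edges, anchor, axis):
    """One axis of the MAE LP: variables = positions + slack pair per edge."""
    free = [n for n in nodes if n != anchor]
    col = {n: k for k, n in enumerate(free)}
    n, m = len(free), len(edges)
    rows, cols, vals = [], [], []
    b = np.zeros(m)
    for k, (i, j, dx, dy, w) in enumerate(edges):
        d = dx if axis == 0 else dy
        if j != anchor:
            rows.append(k); cols.append(col[j]); vals.append(w)
        if i != anchor:
            rows.append(k); cols.append(col[i]); vals.append(-w)
        # slack pair: s(x_j - x_i) - t + u = s d
        rows.append(k); cols.append(n + k); vals.append(-1.0)
        rows.append(k); cols.append(n + m + k); vals.append(1.0)
        b[k] = w * d
    A = sp.csr_matrix((vals, (rows, cols)), shape=(m, n + 2 * m))
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    bounds = [(None, None)] * n + [(0, None)] * (2 * m)
    res = linprog(c, A_eq=A, b_eq=b, bounds=bounds, method="highs")
    if not res.success:  # cannot occur: slacks make every system feasible
        raise RuntimeError(f"LP solve failed: {res.message}")
    out = {anchor: 0.0}
    for node, k in col.items():
        out[node] = float(res.x[k])
    return out, float(res.fun)


def _solve_axis_mse(nodes, edges, anchor, axis):
    free = [n for n in nodes if n != anchor]
    col = {n: k for k, n in enumerate(free)}
    rows, cols, vals = [], [], []
    b = np.zeros(len(edges))
    for k, (i, j, dx, dy, w) in enumerate(edges):
        d = dx if axis == 0 else dy
        if j != anchor:
            rows.append(k); cols.append(col[j]); vals.append(w)
        if i != anchor:
            rows.append(k); cols.append(col[i]); vals.append(-w)
        b[k] = w * d
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(edges), len(free)))
    sol = lsqr(A, b, atol=1e-12, btol=1e-12)[0]
    out = {anchor: 0.0}
    for node, k in col.items():
        out[node] = float(sol[k])
    return out


def _solve_spanning_tree(nodes, edges, anchor):
    """Positions by accumulating offsets along the maximum-score spanning tree.

    Kruskal with ties broken by the smaller (i, j) pair, for determinism.
    """
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    adj: dict[int, list[tuple[int, float, float]]] = {n: [] for n in nodes}
    for i, j, dx, dy, w in sorted(edges, key=lambda e: (-e[4], e[0], e[1])):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            adj[i].append((j, dx, dy))
            adj[j].append((i, -dx, -dy))
    pos = {anchor: np.zeros(2)}
    stack = [anchor]
    while stack:
        u = stack.pop()
        for v, dx, dy in adj[u]:
            if v not in pos:
                pos[v] = pos[u] + (dx, dy)
                stack.append(v)
    return pos


def solve_positions(
    graph: ConstraintGraph,
    method: str = "mae",
    anchor: int | None = None,
) -> GlobalLayout:
    """Solve the constraint system for global float positions.

    ``method`` is one of ``mae`` (LP on absolute residuals, the default),
    ``mse`` (weighted least squares on the same rows) or ``spanning_tree``
    (offsets accumulated along the maximum-score spanning tree).  A
    disconnected graph is solved per component, with a warning; secondary
    components are anchored at their smallest tile id.
    """
    edges = _edges(graph)
    if not edges and len(graph.tiles) > 1:
        raise ValueError("no active constraints to solve")
    nodes = graph.node_ids
    if anchor is None:
        anchor = min(t.id for t in graph.tiles.by_cycle(graph.tiles.cycles[0]))
    comps = _components(nodes, edges)
    if len(comps) > 1:
        warnings.warn(f"constraint graph has {len(comps)} components; solving each independently")

    positions: dict[int, np.ndarray] = {}
    for comp in comps:
        comp_anchor = anchor if anchor in comp else min(comp)
        comp_edges = [e for e in edges if e[0] in comp]
        if len(comp) == 1:
            positions[comp[0]] = np.zeros(2)
            continue
        if method == "mae":
            px, _ = _solve_axis_mae(comp, comp_edges, comp_anchor, 0)
            py, _ = _solve_axis_mae(comp, comp_edges, comp_anchor, 1)
            for n in comp:
                positions[n] = np.array([px[n], py[n]])
        elif method == "mse":
            px = _solve_axis_mse(comp, comp_edges, comp_anchor, 0)
            py = _solve_axis_mse(comp, comp_edges, comp_anchor, 1)
            for n in comp:
                positions[n] = np.array([px[n], py[n]])
        elif method == "spanning_tree":
            pos = _solve_spanning_tree(comp, comp_edges, comp_anchor)
            positions.update(pos)
        else:
            raise ValueError(f"unknown method {method!r}")
    # re-anchor (components other than the anchor's are already at their own
    # local anchor; the global anchor must sit at exactly (0, 0))
    shift = positions[anchor].copy()
    for n in positions:
        positions[n] = positions[n] - shift
    return GlobalLayout(
        positions=positions,
        anchor=anchor,
        method=method,
        objective=mae_objective(graph, positions),
        graph=graph,
    )


def _solve_axis_ilp(nodes, edges, anchor, axis, time_limit):
    free = [n for n in nodes if n != anchor]
    col = {n: k for k, n in enumerate(free)}
    n, m = len(free), len(edges)
    rows, cols, vals = [], [], []
    b = np.zeros(m)
    for k, (i, j, dx, dy, w) in enumerate(edges):
        d = dx if axis == 0 else dy
        if j != anchor:
            rows.append(k); cols.append(col[j]); vals.append(w)
        if i != anchor:
            rows.append(k); cols.append(col[i]); vals.append(-w)
        rows.append(k); cols.append(n + k); vals.append(-1.0)
        rows.append(k); cols.append(n + m + k); vals.append(1.0)
        b[k] = w * d
    A = sp.csr_matrix((vals, (rows, cols)), shape=(m, n + 2 * m))
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    integrality = np.concatenate([np.ones(n), np.zeros(2 * m)])
    lb = np.concatenate([np.full(n, -np.inf), np.zeros(2 * m)])
    ub = np.full(n + 2 * m, np.inf)
    res = milp(
        c,
        constraints=LinearConstraint(A, b, b),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": time_limit},
    )
    if res.status != 0 or res.x is None:
        return None
    out = {anchor: 0.0}
    for node, k in col.items():
        out[node] = float(round(res.x[k]))
    return out


def integerize_positions(
    layout: GlobalLayout,
    method: str = "round",
    time_limit: float = 300.0,
) -> GlobalLayout:
    """Snap solved positions to the integer pixel grid.

    ``round`` rounds each coordinate to the nearest integer after
    re-anchoring.  ``ilp`` re-solves the MAE program with integrality on the
    positions (objective never worse than rounding); if the integer solve
    exceeds ``time_limit`` seconds it falls back to rounding with a warning.
    """
    if layout.graph is None:
        raise ValueError("layout lost its constraint graph; cannot integerize")
    graph = layout.graph
    anchor = layout.anchor
    if method == "round":
        ints = {
            n: np.round(p - layout.positions[anchor]).astype(int)
            for n, p in layout.positions.items()
        }
    elif method == "ilp":
        edges = _edges(graph)
        comps = _components(graph.node_ids, edges)
        ints = {}
        ok = True
        for comp in comps:
            comp_anchor = anchor if anchor in comp else min(comp)
            comp_edges = [e for e in edges if e[0] in comp]
            if len(comp) == 1:
                ints[comp[0]] = np.zeros(2, dtype=int)
                continue
            px = _solve_axis_ilp(comp, comp_edges, comp_anchor, 0, time_limit)
            py = _solve_axis_ilp(comp, comp_edges, comp_anchor, 1, time_limit)
            if px is None or py is None:
                ok = False
                break
            for n in comp:
                ints[n] = np.array([int(px[n]), int(py[n])])
        if not ok:
            warnings.warn("integer LP did not finish; falling back to rounding")
            return integerize_positions(layout, method="round")
    else:
        raise ValueError(f"unknown integerization method {method!r}")
    shift = ints[anchor].copy()
    ints = {n: p - shift for n, p in ints.items()}
    layout.positions_int = ints
    layout.int_method = method
    layout.objective_int = mae_objective(graph, ints)
    return layout


def merge_tiles(
    tiles: TileCollection,
    layout: GlobalLayout,
    mode: str = "mean",
) -> StitchedImage:
    """Assemble per-cycle stitched rasters from integer tile positions.

    ``mean`` averages all tiles contributing to a pixel; ``nearest_center``
    keeps the value from the tile whose center is nearest the pixel.  The
    same frame is used for every cycle and channel, so cycles come out
    mutually aligned.
    """
    if not layout.positions_int:
        raise ValueError("integerize the layout before merging")
    pos = layout.positions_int
    xs0 = [pos[t.id][0] for t in tiles]
    ys0 = [pos[t.id][1] for t in tiles]
    xs1 = [pos[t.id][0] + t.size[0] for t in tiles]
    ys1 = [pos[t.id][1] + t.size[1] for t in tiles]
    ox, oy = int(min(xs0)), int(min(ys0))
    W, H = int(max(xs1)) - ox, int(max(ys1)) - oy
    cycles = tiles.cycles
    n_channels = tiles.tiles[0].n_channels
    data = np.zeros((len(cycles), n_channels, H, W))
    coverage = np.zeros((len(cycles), H, W), dtype=np.int32)

    if mode == "mean":
        for ti, cyc in enumerate(cycles):
            for t in tiles.by_cycle(cyc):
                x, y = pos[t.id] - (ox, oy)
                w, h = t.size
                data[ti, :, y : y + h, x : x + w] += t.data
                coverage[ti, y : y + h, x : x + w] += 1
            nz = coverage[ti] > 0
            plane = data[ti]
            plane[:, nz] /= coverage[ti][nz]
    elif mode == "nearest_center":
        for ti, cyc in enumerate(cycles):
            best = np.full((H, W), np.inf)
            for t in tiles.by_cycle(cyc):
                x, y = pos[t.id] - (ox, oy)
                w, h = t.size
                cx, cy = x + (w - 1) / 2, y + (h - 1) / 2
                yy, xx = np.mgrid[y : y + h, x : x + w]
                d2 = (yy - cy) ** 2 + (xx - cx) ** 2
                take = d2 < best[y : y + h, x : x + w]
                best[y : y + h, x : x + w][take] = d2[take]
                data[ti, :, y : y + h, x : x + w][:, take] = t.data[:, take]
                coverage[ti, y : y + h, x : x + w] += 1
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    return StitchedImage(
        data=data, origin=(ox, oy), coverage=coverage,
        fiducial_channel=tiles.fiducial_channel,
    )
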