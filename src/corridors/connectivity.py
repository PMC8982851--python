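"""Least-cost and circuit-theory connectivity between two terminal reserves.

The resistance raster is turned into an undirected movement graph: nodes
are valid cells, edges join 8-neighbours (4-neighbour optional), and the
cost of stepping between cells i and j is the mean of their per-cell
resistances times the step length (cell size for rook moves, cell size
times sqrt(2) for diagonal moves), expressed in cost-weighted km. Each
terminal reserve is contracted to a single supernode, so movement inside
a reserve is free and the reserve acts as a pure endpoint.

Least-cost branch: exact single-source cost-weighted distances (CWD)
from each terminal via Dijkstra; the normalized least-cost corridor
surface is CWD_A + CWD_B - (least-cost path cost), zero along every
optimal path; the "10% corridor" is the lowest-valued area fraction of
that surface.

Circuit branch: edges become resistors of resistance equal to their
cost; with the source supernode held at voltage 1 and the ground at 0,
the graph-Laplacian system gives per-cell voltages and currents and the
effective resistance between the reserves. The current map is reported
normalized to unit net source-to-ground flow, so it is invariant to a
uniform rescaling of the resistance surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import spsolve

from .raster import RasterGrid, TerminalRegion
from .resistance import ResistanceSurface

__all__ = [
    "MovementGraph",
    "CwdMap",
    "CorridorResult",
    "CircuitResult",
    "build_graph",
    "cost_distance",
    "least_cost_corridor",
    "circuit_solve",
    "kirchhoff_residual",
    "run_species_connectivity",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class MovementGraph:
    """Raster movement graph with contracted terminal supernodes.

    Nodes ``0..n_free-1`` are free valid cells; node ``n_free`` is the
    terminal-A supernode and ``n_free + 1`` terminal B. ``edge_cells``
    keeps the original cell pair of every edge so per-cell currents can
    be mapped back after contraction.
    """

    grid: RasterGrid
    terminal_a: TerminalRegion
    terminal_b: TerminalRegion
    n_free: int
    cell_node: np.ndarray = field(repr=False)  # flat cell index -> node (-1 nodata)
    edge_cells: np.ndarray = field(repr=False)  # (m, 2) flat cell indices
    edge_nodes: np.ndarray = field(repr=False)  # (m, 2) node indices
    edge_cost: np.ndarray = field(repr=False)  # (m,) cost-weighted km

    @property
    def n_nodes(self) -> int:
        return self.n_free + 2

    @property
    def source_node(self) -> int:
        return self.n_free

    @property
    def ground_node(self) -> int:
        return self.n_free + 1

    def node_of_terminal(self, terminal: TerminalRegion | str) -> int:
        name = terminal if isinstance(terminal, str) else terminal.name
        if name == self.terminal_a.name:
            return self.source_node
        if name == self.terminal_b.name:
            return self.ground_node
        raise ValueError(f"terminal '{name}' is not part of this graph")


@dataclass
class CwdMap:
    """Cost-weighted distance (cost-weighted km) from one terminal.

    Zero on the terminal's own cells; unreachable cells carry +inf and
    are flagged nodata.
    """

    grid: RasterGrid
    terminal_name: str


@dataclass
class CorridorResult:
    """Normalized least-cost corridor surface and its area slice."""

    nlcc: RasterGrid
    lcp_cost: float
    mask10: np.ndarray
    slice_fraction: float


@dataclass
class CircuitResult:
    """Voltage/current maps and effective resistance between terminals.

    ``current`` is normalized to unit net source-to-ground flow;
    ``voltage`` has the source supernode at 1 and the ground at 0.
    A disconnected terminal pair yields ``effective_resistance = inf``
    with empty maps.
    """

    voltage: RasterGrid
    current: RasterGrid
    effective_resistance: float
    connected: bool = True
    node_voltage: np.ndarray | None = field(default=None, repr=False)


def _coalesce(i: np.ndarray, j: np.ndarray, w: np.ndarray, reduce: str):
    """Merge parallel edges between the same node pair (min cost for
    shortest paths, summed conductance for circuits)."""
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    order = np.lexsort((hi, lo))
    lo, hi, w = lo[order], hi[order], w[order]
    first = np.ones(len(lo), dtype=bool)
    first[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
    starts = np.flatnonzero(first)
    if reduce == "min":
        red = np.minimum.reduceat(w, starts)
    elif reduce == "sum":
        red = np.add.reduceat(w, starts)
    else:  # pragma: no cover
        raise ValueError(reduce)
    return lo[starts], hi[starts], red


def build_graph(
    res: ResistanceSurface,
    a: TerminalRegion,
    b: TerminalRegion,
    connectivity: int = 8,
) -> MovementGraph:
    """Build the movement graph for a resistance surface and two terminals."""
    grid = res.grid
    valid = grid.valid_mask
    for t in (a, b):
        if t.mask.shape != grid.shape:
            raise ValueError(f"terminal '{t.name}' shape mismatch")
        if not t.mask.any():
            raise ValueError(f"terminal '{t.name}' is empty")
        if np.any(t.mask & ~valid):
            raise ValueError(f"terminal '{t.name}' overlaps nodata cells")
    a.require_disjoint(b)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    r = grid.values
    if np.any(r[valid] <= 0):
        raise ValueError("resistance must be strictly positive on valid cells")

    n_rows, n_cols = grid.shape
    cell_km = grid.cell_size / 1000.0
    free = valid & ~a.mask & ~b.mask
    cell_node = np.full(n_rows * n_cols, -1, dtype=np.int64)
    n_free = int(free.sum())
    cell_node[free.ravel()] = np.arange(n_free)
    cell_node[a.mask.ravel()] = n_free
    cell_node[b.mask.ravel()] = n_free + 1

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, _SQRT2), (1, -1, _SQRT2)]

    flat = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    cells1, cells2, costs = [], [], []
    for dr, dc, f in offsets:
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        both = valid[r0, c0] & valid[r1, c1]
        i1 = flat[r0, c0][both]
        i2 = flat[r1, c1][both]
        cost = 0.5 * (r.ravel()[i1] + r.ravel()[i2]) * f * cell_km
        cells1.append(i1)
        cells2.append(i2)
        costs.append(cost)

    c1 = np.concatenate(cells1) if cells1 else np.empty(0, dtype=np.int64)
    c2 = np.concatenate(cells2) if cells2 else np.empty(0, dtype=np.int64)
    cost = np.concatenate(costs) if costs else np.empty(0)
    u = cell_node[c1]
    v = cell_node[c2]
    keep = u != v  # drop edges internal to one contracted terminal
    return MovementGraph(
        grid=grid,
        terminal_a=a,
        terminal_b=b,
        n_free=n_free,
        cell_node=cell_node,
        edge_cells=np.column_stack([c1[keep], c2[keep]]),
        edge_nodes=np.column_stack([u[keep], v[keep]]),
        edge_cost=cost[keep],
    )


def _shortest_path_matrix(g: MovementGraph) -> csr_matrix:
    lo, hi, w = _coalesce(g.edge_nodes[:, 0], g.edge_nodes[:, 1], g.edge_cost, "min")
    n = g.n_nodes
    return csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([lo, hi]), np.concatenate([hi, lo]))),
        shape=(n, n),
    )


def cost_distance(g: MovementGraph, from_terminal: TerminalRegion | str) -> CwdMap:
    """Exact cost-weighted distance from a terminal supernode (Dijkstra)."""
    src = g.node_of_terminal(from_terminal)
    mat = _shortest_path_matrix(g)
    dist = dijkstra(mat, directed=False, indices=src)
    values = np.full(g.grid.shape, np.inf).ravel()
    has_node = g.cell_node >= 0
    values[has_node] = dist[g.cell_node[has_node]]
    values = values.reshape(g.grid.shape)
    nodata = g.grid.nodata_mask | ~np.isfinite(values)
    name = (
        from_terminal if isinstance(from_terminal, str) else from_terminal.name
    )
    return CwdMap(
        grid=RasterGrid(
            values=np.where(nodata, np.inf, values),
            origin_x=g.grid.origin_x,
            origin_y=g.grid.origin_y,
            cell_size=g.grid.cell_size,
            nodata_mask=nodata,
            crs_label=g.grid.crs_label,
        ),
        terminal_name=name,
    )


def least_cost_corridor(
    cwd_a: CwdMap,
    cwd_b: CwdMap,
    slice_fraction: float = 0.10,
    method: str = "area",
    exclude_terminals: bool = True,
) -> CorridorResult:
    """Normalized least-cost corridor and its sliced binary corridor.

    ``nlcc = CWD_A + CWD_B - lcp_cost`` is zero along every optimal path.
    With ``method='area'`` (default) the corridor mask keeps the cells in
    the lowest ``slice_fraction`` quantile of finite nlcc values, ties at
    the boundary included; ``method='cost_ratio'`` instead keeps cells
    with ``nlcc <= slice_fraction * lcp_cost``.

    A corridor links the two reserves, so by default the reserves'
    interior cells (CWD zero from their own terminal) do not take part in
    the slice: otherwise the reserves themselves, whose corridor depth is
    trivially zero, would consume the sliced area. Set
    ``exclude_terminals=False`` to slice over every finite cell.
    """
    cwd_a.grid.require_compatible(cwd_b.grid, "CWD map")
    if not 0 < slice_fraction <= 1:
        raise ValueError("slice_fraction must be in (0, 1]")
    va, vb = cwd_a.grid.values, cwd_b.grid.values
    finite = (
        cwd_a.grid.valid_mask
        & cwd_b.grid.valid_mask
        & np.isfinite(va)
        & np.isfinite(vb)
    )
    if not finite.any():
        raise ValueError("terminals are disconnected: no cell reaches both")
    total = np.where(finite, va + vb, np.inf)
    lcp_cost = float(total[finite].min())
    nlcc = np.where(finite, total - lcp_cost, np.inf)

    sliceable = finite.copy()
    if exclude_terminals:
        sliceable &= (va > 0) & (vb > 0)
        if not sliceable.any():
            sliceable = finite.copy()
    fin_vals = nlcc[sliceable]
    if method == "area":
        k = int(np.ceil(slice_fraction * fin_vals.size))
        thr = float(np.partition(fin_vals, k - 1)[k - 1])
    elif method == "cost_ratio":
        thr = slice_fraction * lcp_cost
    else:
        raise ValueError(f"unknown corridor slicing method '{method}'")
    mask = sliceable & (nlcc <= thr)

    return CorridorResult(
        nlcc=RasterGrid(
            values=nlcc,
            origin_x=cwd_a.grid.origin_x,
            origin_y=cwd_a.grid.origin_y,
            cell_size=cwd_a.grid.cell_size,
            nodata_mask=~finite,
            crs_label=cwd_a.grid.crs_label,
        ),
        lcp_cost=lcp_cost,
        mask10=mask,
        slice_fraction=slice_fraction,
    )


def circuit_solve(
    g: MovementGraph,
    source: TerminalRegion | str | None = None,
    ground: TerminalRegion | str | None = None,
) -> CircuitResult:
    """Solve the resistor-network model of the movement graph.

    Every edge is a resistor of resistance equal to its traversal cost
    (parallel edges created by terminal contraction combine by summed
    conductance). The source supernode is held at voltage 1 and the
    ground at 0; the interior voltages solve the graph-Laplacian system.
    """
    src = g.source_node if source is None else g.node_of_terminal(source)
    gnd = g.ground_node if ground is None else g.node_of_terminal(ground)
    if src == gnd:
        raise ValueError("source and ground must differ")

    lo, hi, cond = _coalesce(
        g.edge_nodes[:, 0], g.edge_nodes[:, 1], 1.0 / g.edge_cost, "sum"
    )
    n = g.n_nodes
    adj = csr_matrix(
        (
            np.concatenate([cond, cond]),
            (np.concatenate([lo, hi]), np.concatenate([hi, lo])),
        ),
        shape=(n, n),
    )
    n_comp, labels = connected_components(adj, directed=False)
    if labels[src] != labels[gnd]:
        empty = g.grid.with_values(
            np.zeros(g.grid.shape), nodata_mask=np.ones(g.grid.shape, dtype=bool)
        )
        return CircuitResult(
            voltage=empty,
            current=empty,
            effective_resistance=float("inf"),
            connected=False,
        )

    in_comp = labels == labels[src]
    deg = np.asarray(adj.sum(axis=1)).ravel()
    voltage = np.full(n, np.nan)
    voltage[src], voltage[gnd] = 1.0, 0.0
    unknown = np.flatnonzero(in_comp)
    unknown = unknown[(unknown != src) & (unknown != gnd)]
    if unknown.size:
        from scipy.sparse import diags

        lap = (diags(deg) - adj).tocsr()
        sub = lap[unknown][:, unknown].tocsc()
        rhs = -np.asarray(lap[unknown][:, [src]].todense()).ravel()
        voltage[unknown] = spsolve(sub, rhs)

    # total current leaving the source (unnormalized, V = 1 across)
    inc_src = (lo == src) | (hi == src)
    other = np.where(lo[inc_src] == src, hi[inc_src], lo[inc_src])
    i_total = float(np.sum((1.0 - voltage[other]) * cond[inc_src]))
    r_eff = np.inf if i_total <= 0 else 1.0 / i_total

    # per-cell current: half the summed absolute incident edge currents,
    # mapped through the original (pre-contraction) cell pairs and
    # normalized to unit net source-to-ground flow
    u, v = g.edge_nodes[:, 0], g.edge_nodes[:, 1]
    edge_i = (voltage[u] - voltage[v]) / g.edge_cost
    edge_i = np.nan_to_num(edge_i, nan=0.0)
    cell_current = np.zeros(g.grid.n_rows * g.grid.n_cols)
    np.add.at(cell_current, g.edge_cells[:, 0], 0.5 * np.abs(edge_i))
    np.add.at(cell_current, g.edge_cells[:, 1], 0.5 * np.abs(edge_i))
    if i_total > 0:
        cell_current /= i_total
    cell_current = cell_current.reshape(g.grid.shape)

    volt_cells = np.full(g.grid.n_rows * g.grid.n_cols, np.nan)
    has_node = g.cell_node >= 0
    volt_cells[has_node] = voltage[g.cell_node[has_node]]
    volt_cells = volt_cells.reshape(g.grid.shape)
    nodata = g.grid.nodata_mask | ~np.isfinite(volt_cells)

    return CircuitResult(
        voltage=RasterGrid(
            values=np.where(nodata, 0.0, volt_cells),
            origin_x=g.grid.origin_x,
            origin_y=g.grid.origin_y,
            cell_size=g.grid.cell_size,
            nodata_mask=nodata,
            crs_label=g.grid.crs_label,
        ),
        current=RasterGrid(
            values=np.where(nodata, 0.0, cell_current),
            origin_x=g.grid.origin_x,
            origin_y=g.grid.origin_y,
            cell_size=g.grid.cell_size,
            nodata_mask=nodata,
            crs_label=g.grid.crs_label,
        ),
        effective_resistance=float(r_eff),
        connected=True,
        node_voltage=voltage,
    )


def kirchhoff_residual(g: MovementGraph, result: CircuitResult) -> float:
    """Maximum absolute net current injected at any interior node,
    relative to the total source-to-ground current (0 for an exact solve)."""
    if not result.connected or result.node_voltage is None:
        return 0.0
    lo, hi, cond = _coalesce(
        g.edge_nodes[:, 0], g.edge_nodes[:, 1], 1.0 / g.edge_cost, "sum"
    )
    v = result.node_voltage
    net = np.zeros(g.n_nodes)
    flow = (v[lo] - v[hi]) * cond
    flow = np.nan_to_num(flow, nan=0.0)
    np.add.at(net, lo, flow)
    np.add.at(net, hi, -flow)
    interior = np.ones(g.n_nodes, dtype=bool)
    interior[[g.source_node, g.ground_node]] = False
    interior &= np.isfinite(v)
    total = abs(net[g.source_node])
    scale = total if total > 0 else 1.0
    return float(np.max(np.abs(net[interior])) / scale) if interior.any() else 0.0


def run_species_connectivity(
    res: ResistanceSurface,
    a: TerminalRegion,
    b: TerminalRegion,
    slice_fraction: float = 0.10,
    connectivity: int = 8,
) -> tuple[CorridorResult, CircuitResult]:
    """Both connectivity products for one resistance surface."""
    g = build_graph(res, a, b, connectivity=connectivity)
    cwd_a = cost_distance(g, a)
    cwd_b = cost_distance(g, b)
    corridor = least_cost_corridor(cwd_a, cwd_b, slice_fraction=slice_fraction)
    circuit = circuit_solve(g, a, b)
    return corridor, circuit
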