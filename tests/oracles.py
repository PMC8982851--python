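"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the production graph-construction and solver
code paths: edges are enumerated with plain Python loops, shortest
paths come from Bellman-Ford relaxation, and circuit voltages come
from a dense Laplacian pseudo-inverse.
"""

from __future__ import annotations

import numpy as np

SQRT2 = float(np.sqrt(2.0))


def _edges(resistance: np.ndarray, valid: np.ndarray, cell_km: float,
           connectivity: int = 8):
    """Plain-loop edge enumeration: ((r1, c1), (r2, c2), cost)."""
    n_rows, n_cols = resistance.shape
    offs = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offs += [(1, 1, SQRT2), (1, -1, SQRT2)]
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            for dr, dc, f in offs:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_rows and 0 <= c2 < n_cols and valid[r2, c2]:
                    cost = 0.5 * (resistance[r, c] + resistance[r2, c2]) * f * cell_km
                    edges.append(((r, c), (r2, c2), cost))
    return edges


def _with_terminal_links(edges, masks):
    """Zero-cost all-pairs links inside each terminal (contraction)."""
    out = list(edges)
    for mask in masks:
        cells = list(zip(*np.nonzero(mask)))
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                out.append((cells[i], cells[j], 0.0))
    return out


def bellman_ford_cwd(
    resistance: np.ndarray,
    valid: np.ndarray,
    source_mask: np.ndarray,
    other_terminal_mask: np.ndarray | None,
    cell_size: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Cost-weighted distance from a (contracted) terminal by exhaustive
    Bellman-Ford relaxation; unreachable cells are +inf."""
    masks = [source_mask]
    if other_terminal_mask is not None:
        masks.append(other_terminal_mask)
    edges = _with_terminal_links(
        _edges(resistance, valid, cell_size / 1000.0, connectivity), masks
    )
    dist = np.full(resistance.shape, np.inf)
    dist[source_mask] = 0.0
    changed = True
    while changed:
        changed = False
        for (a, b, cost) in edges:
            if dist[a] + cost < dist[b] - 1e-15:
                dist[b] = dist[a] + cost
                changed = True
            if dist[b] + cost < dist[a] - 1e-15:
                dist[a] = dist[b] + cost
                changed = True
    dist[~valid] = np.inf
    return dist


def dense_circuit_oracle(
    resistance: np.ndarray,
    valid: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    cell_size: float,
    connectivity: int = 8,
):
    """Voltages (1 at terminal A, 0 at B) and effective resistance from a
    dense Laplacian pseudo-inverse with unit current injection."""
    n_rows, n_cols = resistance.shape
    group = {}
    n_groups = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            if mask_a[r, c]:
                key = "A"
            elif mask_b[r, c]:
                key = "B"
            else:
                key = (r, c)
            if key not in group:
                group[key] = n_groups if key not in ("A", "B") else None
    # assign indices: free cells first, then A, then B
    idx = {}
    k = 0
    for key in group:
        if key not in ("A", "B"):
            idx[key] = k
            k += 1
    idx["A"] = k
    idx["B"] = k + 1
    n = k + 2

    L = np.zeros((n, n))
    for (a, b, cost) in _edges(resistance, valid, cell_size / 1000.0, connectivity):
        ka = "A" if mask_a[a] else ("B" if mask_b[a] else a)
        kb = "A" if mask_a[b] else ("B" if mask_b[b] else b)
        i, j = idx[ka], idx[kb]
        if i == j:
            continue
        g = 1.0 / cost
        L[i, i] += g
        L[j, j] += g
        L[i, j] -= g
        L[j, i] -= g

    inj = np.zeros(n)
    inj[idx["A"]], inj[idx["B"]] = 1.0, -1.0
    # minimum-norm pseudo-inverse solution of the singular Laplacian system
    v, *_ = np.linalg.lstsq(L, inj, rcond=None)
    r_eff = float(v[idx["A"]] - v[idx["B"]])
    # rescale so A sits at 1 and B at 0
    v = (v - v[idx["B"]]) / (v[idx["A"]] - v[idx["B"]])

    volt = np.full(resistance.shape, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            key = "A" if mask_a[r, c] else ("B" if mask_b[r, c] else (r, c))
            volt[r, c] = v[idx[key]]
    return volt, r_eff
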