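"""From-scratch circuit-theory connectivity solver.

A resistance raster is interpreted as a resistor network: every valid
cell is a node, 8-neighbour cell pairs are joined by resistors whose
conductance is the arithmetic mean of the two cell conductances (1/R),
divided by sqrt(2) for diagonal neighbours.  Injecting one unit of
current between a source and a target and solving the graph-Laplacian
system gives per-edge currents; accumulating per-cell current over many
source/target pairs placed around the landscape perimeter yields an
omnidirectional connectivity map in which high current marks cells that
many random-walk pathways traverse.

To keep perimeter-node placement from imprinting on the map, the core
raster is first padded with a buffer filled by resampling the core's own
resistance values, and the accumulated map is divided by the map from an
all-ones (uniform) resistance raster with identical terminals — a null
model that removes geometry-induced current concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .raster import Raster

__all__ = [
    "LatticeGraph",
    "NodeSet",
    "CurrentMap",
    "add_buffer",
    "crop_buffer",
    "place_nodes",
    "build_lattice",
    "solve_pair",
    "cumulative_current",
    "null_normalise",
    "effective_resistance",
]

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# buffering
# ---------------------------------------------------------------------------


def buffer_width(raster: Raster, fraction: float) -> int:
    """Buffer width in cells: ceil(fraction * max grid dimension)."""
    return math.ceil(fraction * max(raster.n_rows, raster.n_cols))


def add_buffer(resistance: Raster, fraction: float = 0.20, seed: int = 0) -> Raster:
    """Pad the raster on all sides with resampled core resistance values.

    The pad width is ``ceil(fraction * max(n_rows, n_cols))``.  Buffer
    cells are drawn with replacement from the empirical distribution of
    the core's valid resistance values, so the buffer has the same value
    proportions as the core and does not bias effective resistance up or
    down.
    """
    if fraction <= 0:
        raise ValueError("buffer fraction must be positive")
    core = resistance.valid_values().astype(float)
    if core.size == 0:
        raise ValueError("empty core raster")
    w = buffer_width(resistance, fraction)
    rng = np.random.default_rng(seed)
    n_rows, n_cols = resistance.shape
    out = np.empty((n_rows + 2 * w, n_cols + 2 * w))
    fill = rng.choice(core, size=out.shape, replace=True)
    out[:] = fill
    out[w : w + n_rows, w : w + n_cols] = resistance.values
    x0, y0 = resistance.origin
    cs = resistance.cell_size
    return Raster(out, cell_size=cs, origin=(x0 - w * cs, y0 - w * cs), nodata=resistance.nodata)


def crop_buffer(current: "CurrentMap | Raster", width: int) -> "CurrentMap | Raster":
    """Remove a buffer of ``width`` cells from all four sides."""
    if isinstance(current, CurrentMap):
        return CurrentMap(
            raster=crop_buffer(current.raster, width),  # type: ignore[arg-type]
            normalised=current.normalised,
            n_pairs=current.n_pairs,
        )
    raster = current
    if width == 0:
        return raster.copy_with(np.asarray(raster.values).copy())
    if width < 0 or 2 * width >= min(raster.shape):
        raise ValueError(f"buffer width {width} incompatible with shape {raster.shape}")
    vals = np.asarray(raster.values)[width:-width, width:-width].copy()
    x0, y0 = raster.origin
    cs = raster.cell_size
    return Raster(vals, cell_size=cs, origin=(x0 + width * cs, y0 + width * cs), nodata=raster.nodata)


# ---------------------------------------------------------------------------
# node placement
# ---------------------------------------------------------------------------


@dataclass
class NodeSet:
    """Terminal cells (row, col) on the raster perimeter."""

    terminals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.terminals)) != len(self.terminals):
            raise ValueError("terminals must be distinct")

    def __len__(self) -> int:
        return len(self.terminals)

    def pairs(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        t = self.terminals
        return [(t[i], t[j]) for i in range(len(t)) for j in range(i + 1, len(t))]


def perimeter_ring(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    """Outermost ring of cells in clockwise order from the top-left corner."""
    if n_rows == 1:
        return [(0, c) for c in range(n_cols)]
    if n_cols == 1:
        return [(r, 0) for r in range(n_rows)]
    ring = [(0, c) for c in range(n_cols)]
    ring += [(r, n_cols - 1) for r in range(1, n_rows)]
    ring += [(n_rows - 1, c) for c in range(n_cols - 2, -1, -1)]
    ring += [(r, 0) for r in range(n_rows - 2, 0, -1)]
    return ring


def place_nodes(buffered: Raster, n: int = 25, seed: int = 0) -> NodeSet:
    """Place ``n`` terminals evenly around the raster perimeter.

    Terminals sit at equal perimeter-arc spacing starting from a seeded
    random rotational offset, giving omnidirectional coverage without a
    preferred direction.  ``n`` terminals drive ``n*(n-1)/2`` pairwise
    solves downstream (25 -> 300).
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    ring = perimeter_ring(*buffered.shape)
    P = len(ring)
    if n > P:
        raise ValueError(f"{n} nodes exceed perimeter length {P}")
    rng = np.random.default_rng(seed)
    offset = float(rng.uniform(0, P))
    step = P / n
    positions = [int(math.floor(offset + k * step)) % P for k in range(n)]
    return NodeSet([ring[p] for p in positions])


# ---------------------------------------------------------------------------
# lattice graph
# ---------------------------------------------------------------------------


@dataclass
class LatticeGraph:
    """Resistor network over the valid cells of a resistance raster."""

    shape: tuple[int, int]
    node_of_cell: np.ndarray  # (n_rows, n_cols) int, -1 for nodata
    cells: np.ndarray  # (n_nodes, 2) row/col per node
    edges_i: np.ndarray
    edges_j: np.ndarray
    conductance: np.ndarray
    geometry: Raster
    _lap: csc_matrix | None = field(default=None, repr=False)
    _factor_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def node_at(self, cell: tuple[int, int]) -> int:
        node = int(self.node_of_cell[cell])
        if node < 0:
            raise ValueError(f"cell {cell} is nodata; no node there")
        return node

    def laplacian(self) -> csc_matrix:
        if self._lap is None:
            n = self.n_nodes
            i, j, c = self.edges_i, self.edges_j, self.conductance
            rows = np.concatenate([i, j, i, j])
            cols = np.concatenate([j, i, i, j])
            vals = np.concatenate([-c, -c, c, c])
            self._lap = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        return self._lap


def build_lattice(resistance: Raster) -> LatticeGraph:
    """Build the 8-neighbour resistor network for a resistance raster.

    Edge conductance between neighbouring cells i, j is the arithmetic
    mean of the cell conductances, ``(1/R_i + 1/R_j) / 2``; diagonal edges
    carry that mean divided by sqrt(2) to account for the longer span.
    Nodata cells carry no node and no edges.
    """
    vals = np.asarray(resistance.values, dtype=float)
    valid = resistance.valid_mask()
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    if np.any(vals[valid] <= 0):
        raise ValueError("resistance values must be positive")
    n_rows, n_cols = vals.shape
    node_of_cell = np.full((n_rows, n_cols), -1, dtype=np.int64)
    rr, cc = np.nonzero(valid)
    node_of_cell[rr, cc] = np.arange(len(rr))
    cond_cell = np.where(valid, 1.0 / np.where(valid, vals, 1.0), 0.0)

    ei, ej, ec = [], [], []
    # (dr, dc, diagonal?) for the 4 forward directions; reverse edges are implied
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        r0, r1 = max(0, -dr), n_rows - max(0, dr)
        c0, c1 = max(0, -dc), n_cols - max(0, dc)
        a = np.s_[r0:r1, c0:c1]
        b = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        both = valid[a] & valid[b]
        if not both.any():
            continue
        ia = node_of_cell[a][both]
        ib = node_of_cell[b][both]
        c = 0.5 * (cond_cell[a][both] + cond_cell[b][both])
        if diag:
            c = c / SQRT2
        ei.append(ia)
        ej.append(ib)
        ec.append(c)
    return LatticeGraph(
        shape=(n_rows, n_cols),
        node_of_cell=node_of_cell,
        cells=np.column_stack([rr, cc]),
        edges_i=np.concatenate(ei),
        edges_j=np.concatenate(ej),
        conductance=np.concatenate(ec),
        geometry=resistance,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def _component_labels(graph: LatticeGraph) -> np.ndarray:
    n = graph.n_nodes
    adj = coo_matrix(
        (np.ones(len(graph.edges_i)), (graph.edges_i, graph.edges_j)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def _grounded_solver(graph: LatticeGraph, ground: int):
    """LU factorisation of the Laplacian with ``ground`` removed (cached)."""
    if ground not in graph._factor_cache:
        L = graph.laplacian()
        keep = np.arange(graph.n_nodes) != ground
        idx = np.nonzero(keep)[0]
        reduced = L[np.ix_(idx, idx)].tocsc()
        graph._factor_cache[ground] = (splu(reduced), idx)
        # keep the cache small: one grounding is enough for pairwise batches
        if len(graph._factor_cache) > 2:
            graph._factor_cache.pop(next(iter(graph._factor_cache)))
    return graph._factor_cache[ground]


def _voltages(graph: LatticeGraph, source: int, target: int, ground: int) -> np.ndarray:
    """Node voltages for unit current injected at source, withdrawn at target.

    The system is grounded at ``ground`` (voltage 0); currents are
    invariant to the grounding choice, which lets one LU factorisation
    serve every terminal pair.
    """
    lu, idx = _grounded_solver(graph, ground)
    pos = np.full(graph.n_nodes, -1, dtype=np.int64)
    pos[idx] = np.arange(len(idx))
    rhs = np.zeros(len(idx))
    if source != ground:
        rhs[pos[source]] += 1.0
    if target != ground:
        rhs[pos[target]] -= 1.0
    v_red = lu.solve(rhs)
    v = np.zeros(graph.n_nodes)
    v[idx] = v_red
    return v


def _cell_current_from_voltages(
    graph: LatticeGraph, v: np.ndarray, source: int, target: int
) -> np.ndarray:
    """Per-node current: half the sum of absolute incident edge currents.

    Source and target read exactly the injected unit, so a straight series
    chain reports the injected current at every cell.
    """
    edge_cur = graph.conductance * np.abs(v[graph.edges_i] - v[graph.edges_j])
    node_cur = np.zeros(graph.n_nodes)
    np.add.at(node_cur, graph.edges_i, edge_cur)
    np.add.at(node_cur, graph.edges_j, edge_cur)
    node_cur *= 0.5
    node_cur[source] = 1.0
    node_cur[target] = 1.0
    return node_cur


def _to_current_raster(graph: LatticeGraph, node_cur: np.ndarray) -> Raster:
    out = np.zeros(graph.shape)
    out[graph.cells[:, 0], graph.cells[:, 1]] = node_cur
    invalid = graph.node_of_cell < 0
    out[invalid] = 0.0
    geom = graph.geometry
    return Raster(out, cell_size=geom.cell_size, origin=geom.origin, nodata=geom.nodata)


def solve_pair(
    graph: LatticeGraph, source: tuple[int, int], target: tuple[int, int]
) -> tuple[np.ndarray, Raster]:
    """Solve one unit-current injection between two cells.

    Returns ``(voltages, current)`` where voltages are per graph node
    (target at 0) and current is a per-cell raster of accumulated
    absolute current.
    """
    s = graph.node_at(source)
    t = graph.node_at(target)
    if s == t:
        raise ValueError("source and target must differ")
    labels = _component_labels(graph)
    if labels[s] != labels[t]:
        raise ValueError(
            f"terminals are disconnected: source in component {labels[s]}, target in component {labels[t]}"
        )
    v = _voltages(graph, s, t, ground=t)
    node_cur = _cell_current_from_voltages(graph, v, s, t)
    return v, _to_current_raster(graph, node_cur)


def effective_resistance(graph: LatticeGraph, source: tuple[int, int], target: tuple[int, int]) -> float:
    """Two-point effective resistance (voltage drop under unit current)."""
    v, _ = solve_pair(graph, source, target)
    return float(v[graph.node_at(source)] - v[graph.node_at(target)])


# ---------------------------------------------------------------------------
# cumulative maps
# ---------------------------------------------------------------------------


@dataclass
class CurrentMap:
    """Accumulated per-cell current over all terminal pairs."""

    raster: Raster
    normalised: bool = False
    n_pairs: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def cumulative_current(graph: LatticeGraph, nodes: NodeSet) -> CurrentMap:
    """Accumulate per-cell current over every unordered terminal pair.

    All terminals must lie in one connected component.  One Laplacian
    factorisation (grounded at the first terminal) is reused for every
    solve.
    """
    terminals = [graph.node_at(t) for t in nodes.terminals]
    labels = _component_labels(graph)
    comps = {labels[t] for t in terminals}
    if len(comps) > 1:
        raise ValueError(f"terminals span {len(comps)} connected components")
    ground = terminals[0]
    total = np.zeros(graph.n_nodes)
    n_pairs = 0
    for a in range(len(terminals)):
        for b in range(a + 1, len(terminals)):
            s, t = terminals[a], terminals[b]
            v = _voltages(graph, s, t, ground=ground)
            total += _cell_current_from_voltages(graph, v, s, t)
            n_pairs += 1
    return CurrentMap(raster=_to_current_raster(graph, total), normalised=False, n_pairs=n_pairs)


def null_current(shape: tuple[int, int], geometry: Raster, nodes: NodeSet) -> CurrentMap:
    """Cumulative current over a uniform all-ones resistance raster."""
    ones = Raster(np.ones(shape), cell_size=geometry.cell_size, origin=geometry.origin, nodata=geometry.nodata)
    return cumulative_current(build_lattice(ones), nodes)


def null_normalise(
    current: CurrentMap,
    graph_shape: tuple[int, int],
    nodes: NodeSet,
    *,
    eps: float = 1e-12,
    null: CurrentMap | None = None,
) -> CurrentMap:
    """Divide a species current map by the all-ones null-model current map.

    The null run uses the same shape and terminal placement, so the ratio
    removes current concentration caused purely by landscape geometry and
    node positions.  Cells with null current below ``eps`` become nodata.
    A precomputed ``null`` map (same shape and nodes) may be supplied to
    amortise the null solve across species.
    """
    if current.raster.shape != graph_shape:
        raise ValueError(f"current map shape {current.raster.shape} != graph shape {graph_shape}")
    if null is None:
        null = null_current(graph_shape, current.raster, nodes)
    if null.raster.shape != graph_shape:
        raise ValueError("null map shape mismatch")
    den = np.asarray(null.raster.values, dtype=float)
    num = np.asarray(current.raster.values, dtype=float)
    nodata = current.raster.nodata
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > eps, num / den, nodata)
    return CurrentMap(raster=current.raster.copy_with(ratio), normalised=True, n_pairs=current.n_pairs)
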