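import numpy as np
import pytest

from circuitshift.raster import Raster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_raster():
    return Raster(np.ones((8, 8)), cell_size=100.0)


def dijkstra_distance(feature_mask: np.ndarray) -> np.ndarray:
    """Independent oracle: multi-source Dijkstra on the 8-neighbour lattice.

    Orthogonal step cost 1, diagonal sqrt(2); distances in cell units.
    """
    import heapq
    import math

    n_rows, n_cols = feature_mask.shape
    dist = np.full((n_rows, n_cols), np.inf)
    heap = []
    for r, c in zip(*np.nonzero(feature_mask)):
        dist[r, c] = 0.0
        heap.append((0.0, int(r), int(c)))
    heapq.heapify(heap)
    steps = [(-1, -1, math.sqrt(2)), (-1, 0, 1), (-1, 1, math.sqrt(2)),
             (0, -1, 1), (0, 1, 1),
             (1, -1, math.sqrt(2)), (1, 0, 1), (1, 1, math.sqrt(2))]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, w in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and d + w < dist[rr, cc]:
                dist[rr, cc] = d + w
                heapq.heappush(heap, (d + w, rr, cc))
    return dist


def dense_pair_currents(graph, source_cell, target_cell):
    """Independent oracle: dense minimum-norm solve of the full singular Laplacian."""
    L = graph.laplacian().toarray()
    s = graph.node_at(source_cell)
    t = graph.node_at(target_cell)
    inj = np.zeros(graph.n_nodes)
    inj[s], inj[t] = 1.0, -1.0
    v, *_ = np.linalg.lstsq(L, inj, rcond=None)
    edge_cur = graph.conductance * np.abs(v[graph.edges_i] - v[graph.edges_j])
    node_cur = np.zeros(graph.n_nodes)
    np.add.at(node_cur, graph.edges_i, edge_cur)
    np.add.at(node_cur, graph.edges_j, edge_cur)
    node_cur *= 0.5
    node_cur[s] = node_cur[t] = 1.0
    out = np.zeros(graph.shape)
    out[graph.cells[:, 0], graph.cells[:, 1]] = node_cur
    return out
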