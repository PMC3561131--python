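"""District adjacency graphs (queen contiguity) and spatial statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = ["AdjacencyGraph", "lattice_queen_adjacency", "polygon_queen_adjacency", "morans_i"]


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive neighbor structure over n districts.

    ``neighbors[i]`` is a sorted integer array of the districts adjacent to
    district i. ``ids`` maps positional index -> external district id.
    """

    neighbors: list[np.ndarray]
    ids: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]
        if self.ids is None:
            self.ids = list(range(self.n))
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"district {self.ids[i]} is its own neighbor")
        w = self.sparse_w()
        if (w != w.T).nnz:
            raise ValueError("adjacency is not symmetric")

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def n_neighbors(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def sparse_w(self) -> sp.csr_matrix:
        """Binary 0/1 adjacency matrix (CSR)."""
        rows, cols = [], []
        for i, nb in enumerate(self.neighbors):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> sp.csr_matrix:
        """Besag precision structure D - W."""
        w = self.sparse_w()
        d = sp.diags(self.n_neighbors.astype(float))
        return (d - w).tocsr()

    def components(self) -> tuple[int, np.ndarray]:
        return connected_components(self.sparse_w(), directed=False)

    def require_connected(self) -> None:
        n_comp, labels = self.components()
        if n_comp > 1:
            groups = [
                [self.ids[i] for i in np.flatnonzero(labels == c)]
                for c in range(n_comp)
            ]
            raise ValueError(
                f"adjacency graph is disconnected ({n_comp} components): {groups}"
            )

    def require_no_islands(self) -> None:
        isolated = [self.ids[i] for i, nb in enumerate(self.neighbors) if len(nb) == 0]
        if isolated:
            raise ValueError(f"island districts with no neighbors: {isolated}")

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper coloring; same-color districts are never adjacent."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i, nb in enumerate(self.neighbors):
            g.add_edges_from((i, int(j)) for j in nb if j > i)
        colors = nx.greedy_color(g, strategy="largest_first")
        n_colors = max(colors.values(), default=0) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == k), dtype=int)
            for k in range(n_colors)
        ]

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges (i < j) by positional index."""
        return [
            (i, int(j)) for i, nb in enumerate(self.neighbors) for j in nb if j > i
        ]


def edge_list_adjacency(edges, ids) -> AdjacencyGraph:
    """Adjacency from an explicit undirected edge list over district ids."""
    ids = list(ids)
    index = {d: i for i, d in enumerate(ids)}
    neighbors: list[set[int]] = [set() for _ in ids]
    for a, b in edges:
        if a not in index or b not in index:
            raise ValueError(f"edge ({a}, {b}) references unknown district")
        if a == b:
            raise ValueError(f"self-edge on district {a}")
        neighbors[index[a]].add(index[b])
        neighbors[index[b]].add(index[a])
    return AdjacencyGraph(
        neighbors=[np.array(sorted(nb), dtype=int) for nb in neighbors],
        ids=ids,
    )


def lattice_queen_adjacency(rows: int, cols: int) -> AdjacencyGraph:
    """Queen contiguity on a rows x cols lattice of rectangular districts."""
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice must contain at least 2 districts for adjacency")
    neighbors = []
    for r in range(rows):
        for c in range(cols):
            nb = [
                rr * cols + cc
                for rr in range(max(0, r - 1), min(rows, r + 2))
                for cc in range(max(0, c - 1), min(cols, c + 2))
                if (rr, cc) != (r, c)
            ]
            neighbors.append(np.array(sorted(nb), dtype=int))
    return AdjacencyGraph(neighbors=neighbors)


def polygon_queen_adjacency(polygons, ids=None) -> AdjacencyGraph:
    """Queen contiguity between shapely polygons.

    Two districts are adjacent if their boundaries share any point -- a
    border segment or a single corner both count.
    """
    from shapely.strtree import STRtree

    polygons = list(polygons)
    n = len(polygons)
    if ids is None:
        ids = list(range(n))
    tree = STRtree(polygons)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, poly in enumerate(polygons):
        for j in tree.query(poly):
            j = int(j)
            if j == i:
                continue
            if poly.intersects(polygons[j]) and not poly.overlaps(polygons[j]):
                neighbors[i].add(j)
            elif poly.overlaps(polygons[j]):
                # tolerate slight sliver overlaps from digitization
                neighbors[i].add(j)
    graph = AdjacencyGraph(
        neighbors=[np.array(sorted(nb), dtype=int) for nb in neighbors], ids=ids
    )
    return graph


def morans_i(values, graph: AdjacencyGraph) -> float:
    """Moran's I under binary queen weights.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] != graph.n:
        raise ValueError("values length does not match graph size")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant field")
    w = graph.sparse_w()
    s0 = w.sum()
    num = float(z @ (w @ z))
    return (graph.n / s0) * num / denom
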