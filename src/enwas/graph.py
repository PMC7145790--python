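"""Areal adjacency graphs.

The areal units of the analysis (districts, wards, tracts ...) are held as an
:class:`AreaGraph`: an ordered list of area identifiers plus a symmetric
first-order neighbour structure.  Every spatially structured computation in
the package (ICAR scaling, BYM2 fitting, synthetic field generation) runs on
this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay


class GraphError(ValueError):
    """Raised when an adjacency structure violates the AreaGraph contract."""


@dataclass(frozen=True)
class AreaGraph:
    """Ordered areal units with symmetric adjacency.

    Parameters
    ----------
    area_ids
        Unique ordered identifiers, one per areal unit.
    neighbours
        Mapping ``area_id -> tuple of neighbouring area_ids``.  Must be
        symmetric, free of self-loops, and refer only to known ids.
    """

    area_ids: tuple[str, ...]
    neighbours: dict[str, tuple[str, ...]] = field(hash=False)

    def __post_init__(self) -> None:
        ids = self.area_ids
        if len(set(ids)) != len(ids):
            raise GraphError("area_ids must be unique")
        known = set(ids)
        if set(self.neighbours) != known:
            raise GraphError("neighbours must have exactly one entry per area")
        for i, nbrs in self.neighbours.items():
            if i in nbrs:
                raise GraphError(f"self-loop at area {i!r}")
            for j in nbrs:
                if j not in known:
                    raise GraphError(f"unknown neighbour {j!r} of area {i!r}")
                if i not in self.neighbours[j]:
                    raise GraphError(f"asymmetric adjacency: {i!r}~{j!r} but not {j!r}~{i!r}")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def index(self) -> dict[str, int]:
        return {a: k for k, a in enumerate(self.area_ids)}

    def adjacency(self) -> sparse.csr_matrix:
        """Binary adjacency matrix in area order (CSR)."""
        idx = self.index
        rows, cols = [], []
        for i, nbrs in self.neighbours.items():
            for j in nbrs:
                rows.append(idx[i])
                cols.append(idx[j])
        data = np.ones(len(rows))
        n = self.n_areas
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        return np.array([len(self.neighbours[a]) for a in self.area_ids], dtype=float)

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of positional indices.

        Deterministic: components ordered by their smallest member index,
        members sorted within each component.
        """
        n = self.n_areas
        labels = sparse.csgraph.connected_components(
            self.adjacency() if n > 0 else sparse.csr_matrix((0, 0)), directed=False
        )[1] if n else np.empty(0, dtype=int)
        comps: dict[int, list[int]] = {}
        for k, lab in enumerate(labels):
            comps.setdefault(int(lab), []).append(k)
        out = [np.array(sorted(v), dtype=int) for v in comps.values()]
        out.sort(key=lambda c: int(c[0]))
        return out

    @property
    def n_components(self) -> int:
        return len(self.components())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        for i, nbrs in self.neighbours.items():
            for j in nbrs:
                g.add_edge(i, j)
        return g

    def subgraph(self, keep: list[str]) -> "AreaGraph":
        """Induced subgraph on ``keep`` (order preserved from this graph)."""
        keep_set = set(keep)
        ids = tuple(a for a in self.area_ids if a in keep_set)
        nbrs = {a: tuple(j for j in self.neighbours[a] if j in keep_set) for a in ids}
        return AreaGraph(ids, nbrs)

    @classmethod
    def from_edges(cls, area_ids: list[str], edges: list[tuple[str, str]]) -> "AreaGraph":
        nbrs: dict[str, set[str]] = {a: set() for a in area_ids}
        for i, j in edges:
            if i == j:
                raise GraphError(f"self-loop at area {i!r}")
            nbrs[i].add(j)
            nbrs[j].add(i)
        return cls(tuple(area_ids), {a: tuple(sorted(v)) for a, v in nbrs.items()})


def _lattice_dims(n_areas: int) -> tuple[int, int]:
    rows = max(1, int(np.floor(np.sqrt(n_areas))))
    cols = int(np.ceil(n_areas / rows))
    return rows, cols


def simulate_graph(n_areas: int, layout: str = "lattice", seed: int = 0) -> AreaGraph:
    """Generate a connected planar areal adjacency graph.

    ``lattice`` lays the first ``n_areas`` cells of a near-square grid in
    row-major order (rook adjacency); ``random-planar`` triangulates
    ``n_areas`` uniform random points (Delaunay), giving an irregular planar
    graph closer in flavour to a real administrative map.

    Deterministic given ``seed``; the lattice layout ignores the seed.
    """
    if n_areas < 2:
        raise ValueError("n_areas must be at least 2")
    area_ids = [f"A{k:04d}" for k in range(n_areas)]
    if layout == "lattice":
        rows, cols = _lattice_dims(n_areas)
        edges = []
        for k in range(n_areas):
            r, c = divmod(k, cols)
            if c + 1 < cols and k + 1 < n_areas:
                edges.append((area_ids[k], area_ids[k + 1]))
            if (r + 1) * cols + c < n_areas:
                edges.append((area_ids[k], area_ids[(r + 1) * cols + c]))
        return AreaGraph.from_edges(area_ids, edges)
    if layout == "random-planar":
        rng = np.random.default_rng(seed)
        pts = rng.random((n_areas, 2))
        if n_areas < 4:
            # Delaunay needs >=3 non-collinear points; chain tiny graphs.
            edges = [(area_ids[k], area_ids[k + 1]) for k in range(n_areas - 1)]
            return AreaGraph.from_edges(area_ids, edges)
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((int(simplex[a]), int(simplex[b])))
                    edges.add((area_ids[i], area_ids[j]))
        return AreaGraph.from_edges(area_ids, sorted(edges))
    raise ValueError(f"unknown layout {layout!r}")


def greedy_colouring(graph: AreaGraph) -> np.ndarray:
    """Proper vertex colouring (no two neighbours share a colour).

    Used to batch single-site MCMC updates: all areas of one colour have
    conditionally independent full conditionals and can be updated in a
    single vectorised step.  Deterministic (largest-first greedy).
    """
    g = graph.to_networkx()
    col = nx.coloring.greedy_color(g, strategy="largest_first")
    idx = graph.index
    out = np.zeros(graph.n_areas, dtype=int)
    for a, c in col.items():
        out[idx[a]] = c
    return out
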