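"""Neighbourhood structure for the conditional-autoregressive prior.

The intrinsic CAR prior needs, for every region ``i``, its neighbour set
``delta_i`` and neighbour count ``n_delta_i``.  We ingest adjacency as a
GAL-style text file or a two-column edge list (contiguity computed from
polygons is out of scope — that happens upstream in GIS tooling), and can
generate rook-contiguity lattices for synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyStructure",
    "read_adjacency",
    "write_gal",
    "rook_lattice",
    "neighbor_mean",
]


@dataclass
class AdjacencyStructure:
    """Symmetric, irreflexive neighbour lists over an ordered region roster."""

    region_ids: list[str]
    neighbors: list[np.ndarray]  # per-region sorted arrays of neighbor indices
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.region_ids = [str(r) for r in self.region_ids]
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        self.neighbors = [np.asarray(sorted(set(map(int, nb))), dtype=int) for nb in self.neighbors]
        if len(self.neighbors) != len(self.region_ids):
            raise ValueError("one neighbor list per region required")
        nsets = [set(nb.tolist()) for nb in self.neighbors]
        for i, nb in enumerate(nsets):
            if i in nb:
                raise ValueError(f"self-loop at region {self.region_ids[i]!r}")
            for j in nb:
                if j < 0 or j >= len(nsets):
                    raise ValueError(f"neighbor index {j} out of range")
                if i not in nsets[j]:
                    raise ValueError(
                        "asymmetric adjacency: "
                        f"{self.region_ids[i]!r} -> {self.region_ids[j]!r} only"
                    )
            if not nb:
                raise ValueError(
                    f"region {self.region_ids[i]!r} has no neighbors; the CAR "
                    "conditional is undefined for islands (link it explicitly)"
                )
        self._index = {r: k for k, r in enumerate(self.region_ids)}

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_neighbors(self) -> np.ndarray:
        """Neighbour counts ``n_delta_i``."""
        return np.array([nb.size for nb in self.neighbors])

    def region_index(self, region_id: str) -> int:
        try:
            return self._index[str(region_id)]
        except KeyError:
            raise KeyError(f"unknown region id {region_id!r}") from None

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges, each unordered pair once, i < j."""
        out = []
        for i, nb in enumerate(self.neighbors):
            out.extend((i, int(j)) for j in nb if i < j)
        return out

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_regions, self.n_regions))
        for i, j in self.edges():
            A[i, j] = A[j, i] = 1.0
        return A

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian ``Q = diag(n_delta) - A`` (the CAR structure matrix)."""
        return np.diag(self.n_neighbors.astype(float)) - self.adjacency_matrix()

    def is_connected(self) -> bool:
        import networkx as nx

        g = nx.Graph(self.edges())
        g.add_nodes_from(range(self.n_regions))
        return nx.is_connected(g)

    def color_classes(self) -> list[np.ndarray]:
        """Greedy proper colouring; regions within a class share no edge.

        Used to vectorise site-wise CAR updates: sites in one class are
        conditionally independent given the rest.
        """
        import networkx as nx

        g = nx.Graph(self.edges())
        g.add_nodes_from(range(self.n_regions))
        coloring = nx.greedy_color(g, strategy="largest_first")
        n_colors = max(coloring.values()) + 1
        return [
            np.array(sorted(i for i, c in coloring.items() if c == k), dtype=int)
            for k in range(n_colors)
        ]


def read_adjacency(path, dialect: str = "gal", region_ids=None) -> AdjacencyStructure:
    """Read a GAL file or an edge-list CSV.

    GAL dialect: a header line with the region count, then per region a line
    ``id n_neighbors`` followed by a line of neighbor ids.  Edge-list dialect:
    CSV with two columns of region ids, one undirected edge per row.

    ``region_ids`` (optional) fixes the roster and its order; ids in the file
    that are not on the roster raise a load error naming the offender.
    """
    if dialect == "gal":
        with open(path) as fh:
            tokens_by_line = [ln.split() for ln in fh if ln.strip()]
        n = int(tokens_by_line[0][0])
        ids, nbr_ids = [], {}
        k = 1
        for _ in range(n):
            rid, cnt = tokens_by_line[k][0], int(tokens_by_line[k][1])
            nbrs = tokens_by_line[k + 1] if cnt > 0 else []
            if len(nbrs) != cnt:
                raise ValueError(f"GAL entry for {rid!r} promises {cnt} neighbors, lists {len(nbrs)}")
            ids.append(rid)
            nbr_ids[rid] = nbrs
            k += 2 if cnt > 0 else 1
            if cnt == 0:
                # zero-neighbour entries have no neighbour line
                nbr_ids[rid] = []
        edges = [(a, b) for a, bs in nbr_ids.items() for b in bs]
    elif dialect == "edge_list":
        df = pd.read_csv(path, header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError("edge list needs two columns")
        edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        ids = list(dict.fromkeys([a for e in edges for a in e]))
    else:
        raise ValueError(f"unknown adjacency dialect {dialect!r}")

    roster = [str(r) for r in region_ids] if region_ids is not None else [str(r) for r in ids]
    index = {r: k for k, r in enumerate(roster)}
    nb = [set() for _ in roster]
    for a, b in edges:
        a, b = str(a), str(b)
        for x in (a, b):
            if x not in index:
                raise ValueError(f"adjacency names unknown region {x!r} (pair {a!r}-{b!r})")
        if a == b:
            raise ValueError(f"self-loop at region {a!r}")
        nb[index[a]].add(index[b])
        nb[index[b]].add(index[a])
    return AdjacencyStructure(roster, [np.array(sorted(s)) for s in nb])


def write_gal(adj: AdjacencyStructure, path) -> None:
    """Write in the GAL dialect understood by :func:`read_adjacency`."""
    with open(path, "w") as fh:
        fh.write(f"{adj.n_regions}\n")
        for i, rid in enumerate(adj.region_ids):
            nbrs = [adj.region_ids[j] for j in adj.neighbors[i]]
            fh.write(f"{rid} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(nbrs) + "\n")


def rook_lattice(nrows: int, ncols: int, ids=None):
    """Rook-contiguity lattice with integer-grid centroids.

    Returns ``(AdjacencyStructure, centroids)`` where centroids is an
    (I, 2) array of (x, y) = (column, row) coordinates.
    """
    if nrows * ncols < 2:
        raise ValueError("lattice needs at least two cells")
    I = nrows * ncols
    if ids is None:
        ids = [f"r{c:03d}" for c in range(I)]
    if len(ids) != I:
        raise ValueError("ids length must equal nrows*ncols")

    def cell(r, c):
        return r * ncols + c

    nb = [set() for _ in range(I)]
    for r in range(nrows):
        for c in range(ncols):
            i = cell(r, c)
            if r > 0:
                nb[i].add(cell(r - 1, c))
            if r < nrows - 1:
                nb[i].add(cell(r + 1, c))
            if c > 0:
                nb[i].add(cell(r, c - 1))
            if c < ncols - 1:
                nb[i].add(cell(r, c + 1))
    coords = np.array([[i % ncols, i // ncols] for i in range(I)], dtype=float)
    return AdjacencyStructure(list(ids), [np.array(sorted(s)) for s in nb]), coords


def neighbor_mean(values, adj: AdjacencyStructure, region) -> float:
    """Average of ``values`` over the neighbourhood of one region.

    ``region`` may be a positional index or a region id.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != adj.n_regions:
        raise ValueError("values length must match number of regions")
    i = region if isinstance(region, (int, np.integer)) else adj.region_index(region)
    nb = adj.neighbors[i]
    if nb.size == 0:
        raise ValueError("empty neighbor set")
    return float(values[nb].mean())
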