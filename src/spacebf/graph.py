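"""Minimum spanning tree spatial graph and its oriented difference operator.

The fused prior penalizes coefficient differences along the edges of a
spanning graph over the tissue locations.  A minimum spanning tree (MST)
over the pairwise Euclidean distances is used as the backbone: it is
acyclic (no hidden linear constraints among edge differences), connects
every location, and yields the sparsest possible precision matrix.  On
regular grids the MST is not unique because inter-point distances tie;
adding a small seeded jitter to the distances makes it unique and
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = ["MSTGraph", "build_mst", "difference_operator", "read_coords"]


@dataclass(frozen=True)
class MSTGraph:
    """Minimum spanning tree over spatial locations.

    Attributes
    ----------
    n_nodes : int
        Number of locations (vertices).
    edges : ndarray of shape (n_nodes - 1, 2)
        Node-index pairs ``(i1, i2)`` with ``i1 < i2``.
    edge_weights : ndarray of shape (n_nodes - 1,)
        Jittered Euclidean edge lengths (strictly positive).
    jitter_seed : int
        Seed used for the tie-breaking jitter.
    """

    n_nodes: int
    edges: np.ndarray
    edge_weights: np.ndarray
    jitter_seed: int
    # Cached elimination structure (parent array etc.), filled lazily.
    _elim: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.edges.shape != (self.n_nodes - 1, 2):
            raise ValueError("an MST on n nodes must have exactly n-1 edges")

    @property
    def total_weight(self) -> float:
        return float(self.edge_weights.sum())

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric weighted adjacency matrix of the tree."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.edge_weights
        a = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[i, j], np.r_[j, i])),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()

    def elimination_order(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """BFS order (root first), parent array and parent-edge index.

        ``order[0]`` is the root (node 0); ``parent[k]`` is the BFS parent
        of node ``k`` (-1 for the root); ``parent_edge[k]`` indexes the row
        of :attr:`edges` joining ``k`` to its parent.  Used by the exact
        O(n) tree-structured Gaussian sampler.
        """
        if "order" not in self._elim:
            n = self.n_nodes
            neigh: list[list[tuple[int, int]]] = [[] for _ in range(n)]
            for e, (i, j) in enumerate(self.edges):
                neigh[i].append((j, e))
                neigh[j].append((i, e))
            order = np.empty(n, dtype=np.int64)
            parent = np.full(n, -1, dtype=np.int64)
            parent_edge = np.full(n, -1, dtype=np.int64)
            seen = np.zeros(n, dtype=bool)
            order[0] = 0
            seen[0] = True
            head, tail = 0, 1
            while head < tail:
                u = order[head]
                head += 1
                for v, e in neigh[u]:
                    if not seen[v]:
                        seen[v] = True
                        parent[v] = u
                        parent_edge[v] = e
                        order[tail] = v
                        tail += 1
            if tail != n:
                raise ValueError("edge list does not span all nodes")
            self._elim["order"] = order
            self._elim["parent"] = parent
            self._elim["parent_edge"] = parent_edge
        return self._elim["order"], self._elim["parent"], self._elim["parent_edge"]

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a three-column data frame (node1, node2, weight)."""
        return pd.DataFrame(
            {
                "node1": self.edges[:, 0],
                "node2": self.edges[:, 1],
                "weight": self.edge_weights,
            }
        )


def build_mst(
    coords: np.ndarray,
    jitter_scale: float | None = None,
    jitter_seed: int = 0,
) -> MSTGraph:
    """Build the (jitter-uniquified) minimum spanning tree over locations.

    Parameters
    ----------
    coords : array-like of shape (n, 2)
        Planar coordinates of the locations.
    jitter_scale : float, optional
        Scale of the additive uniform jitter applied to pairwise distances
        to break ties (regular grids have massively tied distances).
        Defaults to ``1e-6`` times the median pairwise distance.
    jitter_seed : int
        Seed for the jitter; the result is deterministic given
        ``(coords, jitter_seed)``.

    Returns
    -------
    MSTGraph
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must have shape (n, 2)")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 locations to build a spanning tree")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")

    dist = pdist(coords)
    med = np.median(dist)
    if jitter_scale is None:
        jitter_scale = 1e-6 * med if med > 0 else 1e-6
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be >= 0")
    if jitter_scale == 0 and np.any(dist == 0):
        warnings.warn(
            "duplicated coordinates with jitter_scale=0: MST is ambiguous",
            UserWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(jitter_seed)
    jittered = dist + rng.uniform(0.0, jitter_scale, size=dist.shape)
    full = squareform(jittered)

    tree = minimum_spanning_tree(sparse.csr_matrix(np.triu(full)))
    tree = tree.tocoo()
    i = np.minimum(tree.row, tree.col)
    j = np.maximum(tree.row, tree.col)
    order = np.lexsort((j, i))
    edges = np.column_stack([i[order], j[order]]).astype(np.int64)
    weights = np.asarray(tree.data)[order]
    return MSTGraph(n_nodes=n, edges=edges, edge_weights=weights, jitter_seed=jitter_seed)


def difference_operator(g: MSTGraph) -> sparse.csr_matrix:
    """Oriented incidence matrix D of the tree, shape (n-1, n).

    Row ``i`` carries +1 at the lower-index node and -1 at the higher-index
    node of edge ``i``, so ``D @ beta`` is the vector of edge-wise
    coefficient differences.  ``D`` has rank n-1 and null space span{1};
    ``D.T @ D`` is the graph Laplacian of the tree.
    """
    m = g.n_nodes - 1
    rows = np.repeat(np.arange(m), 2)
    cols = g.edges.reshape(-1)
    vals = np.tile([1.0, -1.0], m)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(m, g.n_nodes))


def read_coords(path) -> np.ndarray:
    """Read a two-column numeric coordinate table (header x, y)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("coordinate file must have at least two columns")
    return df.iloc[:, :2].to_numpy(dtype=float)
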