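"""Exact O(n) Gaussian sampling on tree-structured precision matrices.

The full conditional of a coefficient surface is N(Q^{-1} b, Q^{-1}) with
Q = diag(w) + D' S D, where D is the oriented incidence matrix of the MST
and S the diagonal of edge precisions.  Because the graph is a tree, Q can
be factorized with zero fill-in by eliminating nodes leaves-to-root; both
the mean solve and the N(0, Q^{-1}) draw are then O(n).  This is a sparse
Cholesky specialised to trees, written once and jitted with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _tree_gmrf_draw(order, parent, s_node, w, b, eps, out_mu, out_x):
    """One exact draw from N(Q^{-1} b, Q^{-1}); also writes the mean.

    order : BFS node order, root first; parent[k] = BFS parent (-1 at root)
    s_node : s_node[k] = precision of the edge joining k to parent[k]
             (ignored at the root)
    w : per-node diagonal precision (>= 0, at least one > 0)
    b : canonical mean vector (Q mu = b)
    eps : n iid standard normals
    Returns 0 on success, -1 if a pivot is non-positive.
    """
    n = w.shape[0]
    d = np.empty(n)
    bh = np.empty(n)
    for k in range(n):
        d[k] = w[k]
        bh[k] = b[k]
    # add incident edge precisions to the diagonal
    for idx in range(1, n):
        k = order[idx]
        p = parent[k]
        d[k] += s_node[k]
        d[p] += s_node[k]
    # leaf-to-root elimination (reverse BFS order): no fill-in on a tree
    for idx in range(n - 1, 0, -1):
        k = order[idx]
        p = parent[k]
        if d[k] <= 0.0:
            return -1
        u = -s_node[k]
        c = u / d[k]
        d[p] -= u * c
        bh[p] -= c * bh[k]
    root = order[0]
    if d[root] <= 0.0:
        return -1
    out_mu[root] = bh[root] / d[root]
    out_x[root] = eps[root] / np.sqrt(d[root])
    # root-to-leaf back-substitution: mean and N(0, Q^{-1}) noise
    for idx in range(1, n):
        k = order[idx]
        p = parent[k]
        u = -s_node[k]
        sq = np.sqrt(d[k])
        out_mu[k] = (bh[k] - u * out_mu[p]) / d[k]
        out_x[k] = (eps[k] - (u / sq) * out_x[p]) / sq
    for k in range(n):
        out_x[k] += out_mu[k]
    return 0


def tree_gmrf_draw(order, parent, s_node, w, b, eps):
    """Python wrapper returning (draw, mean); raises on bad pivots."""
    n = w.shape[0]
    mu = np.empty(n)
    x = np.empty(n)
    status = _tree_gmrf_draw(
        order,
        parent,
        np.ascontiguousarray(s_node, dtype=np.float64),
        np.ascontiguousarray(w, dtype=np.float64),
        np.ascontiguousarray(b, dtype=np.float64),
        np.ascontiguousarray(eps, dtype=np.float64),
        mu,
        x,
    )
    if status != 0:
        raise FloatingPointError("non-positive pivot in tree factorization")
    return x, mu


@njit(cache=True)
def crt_table_count(counts, r, u):
    """Total Chinese-restaurant-table count for NB dispersion augmentation.

    For each observation with count X_k, tables l_k = sum_{j=0}^{X_k-1}
    Bernoulli(r / (r + j)); ``u`` supplies sum(counts) iid uniforms.
    """
    total = 0
    idx = 0
    for k in range(counts.shape[0]):
        for j in range(counts[k]):
            if u[idx] * (r + j) < r:
                total += 1
            idx += 1
    return total
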