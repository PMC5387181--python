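"""Weighted and binary graph-theory measures on connectome networks.

Conventions (documented, pluggable where they are genuinely a choice):

- Weight-to-length map for geodesics: ``length = 1/weight`` (binary
  networks use unit lengths).  This is the standard convention for
  connectivity weights where a stronger connection means a shorter
  functional distance; an alternative map can be passed to
  :func:`shortest_paths` and :func:`edge_betweenness`.
- Disconnected pairs have infinite distance; global efficiency counts
  them as 0 contribution, characteristic path length averages over
  *finite* distances only (so it stays finite on sparse thresholded
  graphs; disconnection is captured by efficiency instead).
- Weighted clustering is the Onnela geometric-mean form with weights
  rescaled by the maximum weight; binary clustering is the triangle
  ratio.
- Edge betweenness sums, over unordered node pairs, the fraction of
  that pair's geodesics passing through the edge (all co-minimal paths
  counted).
"""

from __future__ import annotations

from typing import Callable, Dict, Optional, Tuple

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from neonet.build import WeightedNetwork


def inverse_length(w: np.ndarray) -> np.ndarray:
    """Default weight-to-length map, 1/w on existing edges."""
    with np.errstate(divide="ignore"):
        return np.where(w > 0, 1.0 / w, 0.0)


def _lengths(net: WeightedNetwork, length_map: Callable = inverse_length) -> np.ndarray:
    if np.any(net.weights < 0):
        raise ValueError("negative weights are not allowed")
    if net.weight_kind == "BINARY":
        return (net.weights > 0).astype(float)
    return length_map(net.weights)


def network_density(net: WeightedNetwork) -> float:
    """Existing edges as a fraction of the N(N-1)/2 possible."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return net.n_edges / (n * (n - 1) / 2)


def total_strength(net: WeightedNetwork) -> float:
    """Sum of all connection weights (each unordered edge once)."""
    return float(np.triu(net.weights, 1).sum())


def shortest_paths(
    net: WeightedNetwork, length_map: Callable = inverse_length
) -> np.ndarray:
    """All-pairs geodesic distance matrix; inf for disconnected pairs."""
    lengths = _lengths(net, length_map)
    return _distances(lengths)


def _distances(lengths: np.ndarray) -> np.ndarray:
    return _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)


def _global_efficiency_from_lengths(lengths: np.ndarray) -> float:
    n = lengths.shape[0]
    if n < 2:
        return 0.0
    d = _distances(lengths)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: WeightedNetwork, length_map: Callable = inverse_length) -> float:
    """Mean inverse geodesic distance over ordered node pairs (1/inf = 0)."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _global_efficiency_from_lengths(_lengths(net, length_map))


def local_efficiency(net: WeightedNetwork, length_map: Callable = inverse_length) -> float:
    """Mean over nodes of the neighbourhood subgraph's global efficiency.

    A node's neighbourhood subgraph is induced on its neighbours with
    the original edge weights; nodes with fewer than two neighbours
    contribute 0.
    """
    if net.n_nodes < 2:
        raise ValueError("local efficiency needs at least 2 nodes")
    lengths = _lengths(net, length_map)
    adj = net.weights > 0
    total = 0.0
    for u in range(net.n_nodes):
        nbrs = np.flatnonzero(adj[u])
        if nbrs.size < 2:
            continue
        total += _global_efficiency_from_lengths(lengths[np.ix_(nbrs, nbrs)])
    return total / net.n_nodes


def characteristic_path_length(
    net: WeightedNetwork, length_map: Callable = inverse_length
) -> float:
    """Mean finite geodesic distance over connected ordered node pairs."""
    if net.n_nodes < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    d = shortest_paths(net, length_map)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return 0.0
    return float(d[finite].mean())


def clustering_coefficient(net: WeightedNetwork) -> float:
    """Average clustering: binary triangle ratio, or Onnela weighted form."""
    if net.n_nodes < 2:
        raise ValueError("clustering needs at least 2 nodes")
    g = nx.from_numpy_array(net.weights)
    if net.is_empty:
        return 0.0
    weight = None if net.weight_kind == "BINARY" else "weight"
    return float(nx.average_clustering(g, weight=weight))


def edge_betweenness(
    net: WeightedNetwork, length_map: Callable = inverse_length
) -> Dict[Tuple[int, int], float]:
    """Per-edge betweenness centrality.

    For each edge, the sum over unordered node pairs of (geodesics
    through the edge) / (all geodesics for that pair), under the 1/w
    length convention (unit lengths for binary networks).  Returned as
    ``{(i, j): value}`` with ``i < j`` for every existing edge.
    """
    lengths = _lengths(net, length_map)
    iu, ju = np.nonzero(np.triu(lengths, 1))
    if iu.size == 0:
        return {}
    g = ig.Graph(n=net.n_nodes, edges=list(zip(iu.tolist(), ju.tolist())))
    if net.weight_kind == "BINARY":
        eb = g.edge_betweenness()
    else:
        eb = g.edge_betweenness(weights=lengths[iu, ju].tolist())
    return {(int(i), int(j)): float(b) for i, j, b in zip(iu, ju, eb)}


METRICS: Dict[str, Callable[[WeightedNetwork], float]] = {
    "density": network_density,
    "total_strength": total_strength,
    "Lp": characteristic_path_length,
    "Cp": clustering_coefficient,
    "Eglob": global_efficiency,
    "Eloc": local_efficiency,
}
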