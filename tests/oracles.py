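"""Independent brute-force reference implementations for small graphs.

Everything here works from first principles (Floyd-Warshall, explicit
simple-path enumeration, hand-written formulas) and shares no code with
the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Tuple

import numpy as np

INF = float("inf")


def fw_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs geodesics by Floyd-Warshall under 1/w edge lengths."""
    n = weights.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_density(weights: np.ndarray) -> float:
    n = weights.shape[0]
    e = sum(1 for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0)
    return e / (n * (n - 1) / 2)


def brute_global_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    d = fw_distances(weights)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    total = 0.0
    for u in range(n):
        nbrs = [v for v in range(n) if weights[u, v] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def brute_path_length(weights: np.ndarray) -> float:
    n = weights.shape[0]
    d = fw_distances(weights)
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and d[i, j] < INF]
    return sum(vals) / len(vals) if vals else 0.0


def brute_clustering(weights: np.ndarray, binary: bool) -> float:
    """Average clustering: triangle ratio, or Onnela with max-weight rescaling."""
    n = weights.shape[0]
    wmax = weights.max()
    total = 0.0
    for u in range(n):
        nbrs = [v for v in range(n) if weights[u, v] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            if weights[a, b] > 0:
                if binary:
                    tri += 1.0
                else:
                    tri += (
                        (weights[u, a] / wmax) * (weights[u, b] / wmax) * (weights[a, b] / wmax)
                    ) ** (1.0 / 3.0)
        total += 2.0 * tri / (k * (k - 1))
    return total / n


def brute_edge_betweenness(
    weights: np.ndarray, binary: bool = False, rtol: float = 1e-12
) -> Dict[Tuple[int, int], float]:
    """Edge betweenness by explicit enumeration of all simple paths.

    For each unordered node pair, every simple path is enumerated, the
    geodesic length found, all co-minimal paths counted (ties within
    relative tolerance ``rtol``), and each geodesic's edges credited
    with 1/(number of geodesics).
    """
    n = weights.shape[0]
    adj = {u: [v for v in range(n) if weights[u, v] > 0] for u in range(n)}

    def edge_len(u: int, v: int) -> float:
        return 1.0 if binary else 1.0 / weights[u, v]

    eb = {
        (i, j): 0.0 for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0
    }

    def all_simple_paths(s: int, t: int) -> List[List[int]]:
        out: List[List[int]] = []

        def extend(path: List[int]) -> None:
            u = path[-1]
            if u == t:
                out.append(list(path))
                return
            for v in adj[u]:
                if v not in path:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return out

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_simple_paths(s, t)
            if not paths:
                continue
            lengths = [sum(edge_len(p[k], p[k + 1]) for k in range(len(p) - 1)) for p in paths]
            best = min(lengths)
            geos = [p for p, l in zip(paths, lengths) if l <= best * (1 + rtol)]
            credit = 1.0 / len(geos)
            for p in geos:
                for k in range(len(p) - 1):
                    e = (min(p[k], p[k + 1]), max(p[k], p[k + 1]))
                    eb[e] += credit
    return eb


def brute_fdr_bh(p_values: np.ndarray, q: float) -> np.ndarray:
    """Step-up rule evaluated literally from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def random_small_graph(rng: np.random.Generator) -> Tuple[np.ndarray, bool]:
    """Random graph with <= 7 nodes; returns (weights, is_binary)."""
    n = int(rng.integers(2, 8))
    p = rng.uniform(0.25, 0.9)
    binary = bool(rng.random() < 0.5)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = 1.0 if binary else rng.uniform(0.1, 5.0)
                w[j, i] = w[i, j]
    return w, binary
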