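"""Density normalisation: cost-corrected sweeps, weight normalisation, null models.

Three complementary ways to compare network topology across subjects
whose raw networks differ in sparsity and total strength:

1. **Cost-correction** — threshold every raw network to the same
   density d by keeping the ``round(d * M)`` edges with the most
   streamlines (M = possible edges), sweep d over a grid (default 0.05
   to 0.50 in 0.01 steps), and summarise each metric by
   *cost-integration*: its arithmetic mean over the grid.
2. **Normalised weights** — at each density, divide the retained
   weights by their sum so every subject has total strength 1; metrics
   then reflect pure weighted topology.
3. **Random equivalents** — compare against degree-preserving rewired
   null networks: normalised path length alpha = Lp/<Lp_rand>,
   normalised clustering gamma = Cp/<Cp_rand>, and the small-world
   coefficient.

Thresholding always ranks edges by streamline count, whatever the
weight kind, with a deterministic tie rule (higher NDI, then
lexicographic (i, j)); this makes retained edge sets nested across the
density grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from neonet.build import WeightedNetwork, build_raw_network
from neonet.cohort import MultiWeightConnectome
from neonet.metrics import (
    METRICS,
    characteristic_path_length,
    clustering_coefficient,
)

DEFAULT_SWEEP_METRICS = ("density", "total_strength", "Lp", "Cp", "Eglob", "Eloc")


def default_density_grid(dmin: float = 0.05, dmax: float = 0.50, dstep: float = 0.01) -> np.ndarray:
    """Strictly increasing density grid, 46 levels with the defaults."""
    n = int(round((dmax - dmin) / dstep)) + 1
    grid = dmin + dstep * np.arange(n)
    if not (0 < grid[0] and grid[-1] <= 1 and np.all(np.diff(grid) > 0)):
        raise ValueError("density grid must be strictly increasing within (0, 1]")
    return grid


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def rank_edges_by_count(net: WeightedNetwork) -> Tuple[np.ndarray, np.ndarray]:
    """Edge ordering used for all count-based thresholding.

    Descending streamline count; ties broken by higher NDI, then by
    lexicographic (i, j).  The fixed ordering makes thresholded edge
    sets nested across densities.
    """
    if net.counts is None:
        raise ValueError("network carries no streamline counts to rank by")
    iu, ju = np.nonzero(np.triu(net.counts, 1))
    counts = net.counts[iu, ju]
    ndi = net.ndi[iu, ju] if net.ndi is not None else np.zeros_like(counts, dtype=float)
    order = np.lexsort((ju, iu, -ndi, -counts))
    return iu[order], ju[order]


@dataclass(frozen=True)
class DensitySweep:
    """Per-density metric values plus their cost-integrated summaries."""

    grid: np.ndarray
    values: pd.DataFrame  # columns: density, metric, value
    weight_kind: str
    normalized: bool

    @property
    def cost_integrated(self) -> Dict[str, float]:
        return {
            metric: float(sub["value"].mean())
            for metric, sub in self.values.groupby("metric", sort=False)
        }

    def metric_series(self, metric: str) -> np.ndarray:
        sub = self.values[self.values["metric"] == metric]
        return sub.sort_values("density")["value"].to_numpy()


def _threshold_from_ranking(
    net: WeightedNetwork, iu: np.ndarray, ju: np.ndarray, d: float
) -> WeightedNetwork:
    n = net.n_nodes
    m = n * (n - 1) // 2
    raw_density = iu.size / m
    if d <= 0 or d > 1:
        raise ValueError(f"density must be in (0, 1], got {d}")
    if raw_density < d - 1e-12:
        raise ValueError(
            f"requested density {d:.3f} exceeds the raw network density "
            f"{raw_density:.3f}; the cost sweep is only feasible up to the "
            "minimum raw density across subjects"
        )
    k = min(_round_half_up(d * m), iu.size)
    sel_i, sel_j = iu[:k], ju[:k]

    def take(mat: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if mat is None:
            return None
        out = np.zeros_like(mat)
        out[sel_i, sel_j] = mat[sel_i, sel_j]
        out[sel_j, sel_i] = mat[sel_j, sel_i]
        return out

    return WeightedNetwork(
        weights=take(net.weights),
        weight_kind=net.weight_kind,
        counts=take(net.counts),
        ndi=take(net.ndi),
        node_labels=net.node_labels,
    )


def threshold_network(net: WeightedNetwork, d: float) -> WeightedNetwork:
    """Keep the round(d * M) edges with the most streamlines."""
    iu, ju = rank_edges_by_count(net)
    return _threshold_from_ranking(net, iu, ju, d)


def cost_threshold(
    connectome: MultiWeightConnectome,
    weight_kind: str,
    d: float,
    min_streamlines: int = 5,
) -> WeightedNetwork:
    """Build the raw network and threshold it to density ``d``."""
    return threshold_network(build_raw_network(connectome, weight_kind, min_streamlines), d)


def normalize_weights(net: WeightedNetwork) -> WeightedNetwork:
    """Divide every retained weight by the sum of retained weights.

    The upper-triangle weights of the result sum to 1 (each unordered
    edge counted once), removing total-strength differences between
    subjects at a fixed density.
    """
    total = np.triu(net.weights, 1).sum()
    if total <= 0:
        raise ValueError("cannot normalise an all-zero weight matrix")
    return WeightedNetwork(
        weights=net.weights / total,
        weight_kind=net.weight_kind,
        counts=net.counts,
        ndi=net.ndi,
        node_labels=net.node_labels,
    )


def cost_integrate(values: Sequence[float], expected_levels: Optional[int] = None) -> float:
    """Arithmetic mean over the density grid; refuses partial averages."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cost integration needs at least one density level")
    if expected_levels is not None and arr.size != expected_levels:
        raise ValueError(
            f"expected {expected_levels} density levels, got {arr.size}; "
            "no silent partial averages"
        )
    if np.any(~np.isfinite(arr)):
        raise ValueError("cost integration over non-finite metric values")
    return float(arr.mean())


def density_sweep(
    connectome: MultiWeightConnectome,
    weight_kind: str,
    grid: Optional[np.ndarray] = None,
    normalize: bool = False,
    metrics: Iterable[str] = DEFAULT_SWEEP_METRICS,
    min_streamlines: int = 5,
) -> DensitySweep:
    """Threshold at every grid density and evaluate the requested metrics.

    Edge ranking is computed once, so the retained edge set at density d
    is a strict superset of that at any lower density.
    """
    if grid is None:
        grid = default_density_grid()
    raw = build_raw_network(connectome, weight_kind, min_streamlines)
    iu, ju = rank_edges_by_count(raw)
    rows = []
    for d in grid:
        net = _threshold_from_ranking(raw, iu, ju, float(d))
        if normalize:
            net = normalize_weights(net)
        for metric in metrics:
            rows.append({"density": float(d), "metric": metric, "value": METRICS[metric](net)})
    return DensitySweep(
        grid=np.asarray(grid, dtype=float),
        values=pd.DataFrame(rows),
        weight_kind=weight_kind,
        normalized=normalize,
    )


def random_equivalent(
    net: WeightedNetwork, seed: int, n_swaps_per_edge: int = 10
) -> WeightedNetwork:
    """Degree-preserving rewired null network with permuted weights.

    The binary topology is rewired by double-edge swaps (each swap
    exactly preserves every node's degree); the original weight
    multiset is then randomly permuted onto the rewired edges, so the
    degree sequence is preserved exactly and the strength distribution
    approximately.  Graphs admitting no legal swap (e.g. a triangle)
    are returned with their topology unchanged.  Deterministic per seed.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    edges = {(int(a), int(b)) for a, b in zip(iu, ju)}
    edge_list = sorted(edges)
    e = len(edge_list)
    target = n_swaps_per_edge * e
    max_attempts = 100 * target
    successes = attempts = 0
    while successes < target and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, e, size=2)
        if k1 == k2:
            continue
        a, b = edge_list[k1]
        c, d = edge_list[k2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if len({a, b, c, d}) < 4:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edges or new2 in edges:
            continue
        edges.discard((a, b) if a < b else (b, a))
        edges.discard((c, d) if c < d else (d, c))
        edges.update((new1, new2))
        edge_list[k1] = new1
        edge_list[k2] = new2
        successes += 1

    weights_pool = net.weights[iu, ju]
    perm = rng.permutation(e)
    new_w = np.zeros_like(net.weights)
    for (a, b), w in zip(edge_list, weights_pool[perm]):
        new_w[a, b] = w
        new_w[b, a] = w
    return WeightedNetwork(weights=new_w, weight_kind=net.weight_kind, node_labels=net.node_labels)


@dataclass(frozen=True)
class SmallWorldResult:
    """Normalised path length, clustering and the small-world coefficient."""

    alpha: float  # Lp / <Lp over random equivalents>
    gamma: float  # Cp / <Cp over random equivalents>
    sigma: float
    n_random: int
    seed: int
    printed_form: bool = False  # True: sigma = alpha/gamma; False: gamma/alpha


def small_world(
    net: WeightedNetwork,
    n_random: int = 100,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
    printed_form: bool = False,
    null_networks: Optional[Sequence[WeightedNetwork]] = None,
) -> SmallWorldResult:
    """Small-world indices against degree-matched rewired nulls.

    ``sigma`` defaults to the conventional gamma/alpha ratio; pass
    ``printed_form=True`` for the reciprocal alpha/gamma form.  Null
    networks that come out disconnected are handled by the finite-pairs
    path-length convention, never as NaN.  An explicit ``null_networks``
    sequence replaces the internally generated rewired ensemble (useful
    for limit checks: comparing a network against itself gives
    alpha = gamma = sigma = 1).
    """
    if null_networks is None and n_random < 1:
        raise ValueError("n_random must be >= 1")
    lp = characteristic_path_length(net)
    cp = clustering_coefficient(net)
    if null_networks is None:
        child_seeds = np.random.SeedSequence(seed).generate_state(n_random) % (2**31)
        null_networks = [random_equivalent(net, int(s), n_swaps_per_edge) for s in child_seeds]
    else:
        n_random = len(null_networks)
    lps, cps = [], []
    for rand in null_networks:
        lps.append(characteristic_path_length(rand))
        cps.append(clustering_coefficient(rand))
    alpha = lp / float(np.mean(lps))
    gamma = cp / float(np.mean(cps))
    sigma = alpha / gamma if printed_form else gamma / alpha
    return SmallWorldResult(
        alpha=alpha, gamma=gamma, sigma=sigma, n_random=n_random, seed=seed,
        printed_form=printed_form,
    )
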