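"""Betweenness-centrality core/local edge decomposition.

At each density, edges are ranked by edge betweenness and the "core" is
the minimal top set accounting for at least a given share (default 50%)
of total betweenness; the remaining edges are "local".  The ranking
breaks betweenness ties lexicographically by edge index, keeping the
core strictly minimal (removing its weakest edge drops the cumulative
share below the threshold); pass ``include_boundary_ties=True`` to
instead include every edge tied with the boundary value, at the cost
of minimality.

By default betweenness is computed with 1/w geodesic lengths taken from
the streamline counts (the quantity networks are thresholded and ranked
by); ``betweenness_on`` switches to the network's own weights or to the
binary topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional, Tuple

import numpy as np
import pandas as pd

from neonet.build import WeightedNetwork
from neonet.metrics import edge_betweenness

Edge = Tuple[int, int]


@dataclass(frozen=True)
class CoreLocalPartition:
    core_edges: FrozenSet[Edge]
    local_edges: FrozenSet[Edge]
    core_betweenness_share: float
    share_requested: float
    all_tied: bool = False  # all betweenness values equal (e.g. all zero)
    density_level: Optional[float] = None

    @property
    def edges(self) -> FrozenSet[Edge]:
        return self.core_edges | self.local_edges


def identify_core(
    net: WeightedNetwork,
    share: float = 0.5,
    betweenness_on: str = "counts",
    density_level: Optional[float] = None,
    include_boundary_ties: bool = False,
) -> CoreLocalPartition:
    """Split edges into the top-betweenness core and the local remainder.

    The core is the minimal prefix of the betweenness-descending edge
    ranking (ties broken lexicographically) whose cumulative
    betweenness reaches ``share`` of the total; with
    ``include_boundary_ties`` it is extended to every edge tied with
    the boundary value.  With all betweenness values tied (a degenerate
    case, e.g. a complete graph where every pair's geodesic is its own
    edge) the result is flagged via ``all_tied``.
    """
    if not 0 < share < 1:
        raise ValueError(f"share must be in (0, 1), got {share}")
    if net.is_empty:
        raise ValueError("core identification needs at least one edge")

    if betweenness_on == "counts" and net.counts is not None:
        bnet = WeightedNetwork(
            weights=net.counts.astype(float), weight_kind=net.weight_kind
        )
        eb = edge_betweenness(bnet)
    elif betweenness_on == "binary":
        bnet = WeightedNetwork(
            weights=(net.weights > 0).astype(float), weight_kind="BINARY"
        )
        eb = edge_betweenness(bnet)
    else:
        eb = edge_betweenness(net)

    edges = sorted(eb, key=lambda e: (-eb[e], e))
    values = np.array([eb[e] for e in edges])
    total = values.sum()
    if total == 0:
        # all-zero betweenness: tie rule alone decides, core = all edges, flagged
        return CoreLocalPartition(
            core_edges=frozenset(edges),
            local_edges=frozenset(),
            core_betweenness_share=1.0,
            share_requested=share,
            all_tied=True,
            density_level=density_level,
        )
    cum = np.cumsum(values)
    k = int(np.searchsorted(cum, share * total - 1e-12 * total) + 1)
    if include_boundary_ties:
        boundary = values[k - 1]
        while k < len(edges) and np.isclose(values[k], boundary, rtol=1e-12, atol=0):
            k += 1
    core = frozenset(edges[:k])
    local = frozenset(edges[k:])
    return CoreLocalPartition(
        core_edges=core,
        local_edges=local,
        core_betweenness_share=float(cum[k - 1] / total),
        share_requested=share,
        all_tied=bool(np.isclose(values[0], values[-1], rtol=1e-12, atol=0)),
        density_level=density_level,
    )


def core_local_medians(
    partition: CoreLocalPartition, weight_net: WeightedNetwork
) -> Tuple[float, float]:
    """Median weight over core and local edge sets, for any weighting.

    An empty side yields NaN (a flagged missing value) rather than an
    error, so sweeps over densities where one side vanishes remain
    usable.
    """

    def side_median(edge_set: FrozenSet[Edge]) -> float:
        if not edge_set:
            return float("nan")
        idx = np.array(sorted(edge_set))
        return float(np.median(weight_net.weights[idx[:, 0], idx[:, 1]]))

    return side_median(partition.core_edges), side_median(partition.local_edges)


def core_local_median_sweep(
    connectome,
    weight_kind: str,
    grid: np.ndarray,
    share: float = 0.5,
    normalize: bool = False,
    min_streamlines: int = 5,
) -> pd.DataFrame:
    """Core/local median weights at each grid density.

    Returns a tidy frame (density, median_core, median_local,
    core_share); cost-integrate the columns with
    :func:`neonet.normalize.cost_integrate`.
    """
    from neonet.build import build_raw_network
    from neonet.normalize import _threshold_from_ranking, normalize_weights, rank_edges_by_count

    raw = build_raw_network(connectome, weight_kind, min_streamlines)
    iu, ju = rank_edges_by_count(raw)
    rows = []
    for d in grid:
        net = _threshold_from_ranking(raw, iu, ju, float(d))
        part = identify_core(net, share=share, density_level=float(d))
        wnet = normalize_weights(net) if normalize else net
        med_core, med_local = core_local_medians(part, wnet)
        rows.append(
            {
                "density": float(d),
                "median_core": med_core,
                "median_local": med_local,
                "core_share": part.core_betweenness_share,
            }
        )
    return pd.DataFrame(rows)
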