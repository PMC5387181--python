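"""Raw weighted network construction from streamline counts and microstructure.

A "raw" network keeps the edges linked by at least ``min_streamlines``
(default 5) streamlines.  Weights are one of:

- ``FS``   — fraction of streamlines, count divided by the total count over
  all surviving unordered edges (upper-triangle weights sum to 1),
- ``FA``   — the edge's median fractional anisotropy,
- ``NDI``  — the edge's median neurite density index,
- ``ODI_C``— fibre coherence, 1 minus the edge's median orientation
  dispersion index,
- ``BINARY`` — 0/1 adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from neonet.cohort import MultiWeightConnectome

WEIGHT_KINDS = ("FS", "FA", "NDI", "ODI_C", "BINARY")


@dataclass(frozen=True)
class WeightedNetwork:
    """One symmetric weighted graph with a weight-kind tag.

    ``counts`` keeps the streamline counts of the surviving edges so
    that later thresholding decisions (which always rank by streamline
    count) can be made on any weighting of the same network.  ``ndi``
    is retained for the documented count-tie rule.
    """

    weights: np.ndarray
    weight_kind: str
    counts: Optional[np.ndarray] = None
    ndi: Optional[np.ndarray] = None
    node_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got {w.shape}")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("self-connections are not allowed (nonzero diagonal)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if self.weight_kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}; expected one of {WEIGHT_KINDS}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def is_empty(self) -> bool:
        return self.n_edges == 0

    def edge_values(self) -> np.ndarray:
        """Weights of existing edges (upper triangle, nonzero only)."""
        ut = np.triu(self.weights, 1)
        return ut[ut > 0]


def build_raw_network(
    connectome: MultiWeightConnectome,
    weight_kind: str,
    min_streamlines: int = 5,
) -> WeightedNetwork:
    """Apply the streamline-count filter and weight the surviving edges.

    Edges with fewer than ``min_streamlines`` streamlines are removed
    before any weight is computed; in particular the FS denominator is
    the total count over surviving edges only, with each unordered edge
    counted once.  An empty post-filter network is returned explicitly
    (``is_empty``), never as silent zeros with a bogus weighting.
    """
    if weight_kind not in WEIGHT_KINDS:
        raise ValueError(f"unknown weight_kind {weight_kind!r}; expected one of {WEIGHT_KINDS}")
    if min_streamlines < 1:
        raise ValueError("min_streamlines must be >= 1")

    counts = connectome.counts
    keep = counts >= min_streamlines
    np.fill_diagonal(keep, False)
    kept_counts = np.where(keep, counts, 0)

    if weight_kind == "FS":
        total = np.triu(kept_counts, 1).sum()
        weights = kept_counts / total if total > 0 else kept_counts.astype(float)
    elif weight_kind == "FA":
        weights = np.where(keep, connectome.fa, 0.0)
    elif weight_kind == "NDI":
        weights = np.where(keep, connectome.ndi, 0.0)
    elif weight_kind == "ODI_C":
        weights = np.where(keep, 1.0 - connectome.odi, 0.0)
    else:  # BINARY
        weights = keep.astype(float)

    return WeightedNetwork(
        weights=weights,
        weight_kind=weight_kind,
        counts=kept_counts,
        ndi=np.where(keep, connectome.ndi, 0.0),
        node_labels=connectome.node_labels,
    )


def median_connectivity(net: WeightedNetwork) -> float:
    """Median weight over the network's existing edges.

    Even edge counts use the mean-of-middle-pair convention (numpy's
    default).  Raises on an edgeless network rather than returning a
    meaningless 0.
    """
    vals = net.edge_values()
    if vals.size == 0:
        raise ValueError("median connectivity is undefined on an edgeless network")
    return float(np.median(vals))
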