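"""CSV and GraphML readers/writers for cohorts and networks.

Two on-disk dialects for a cohort directory, both round-trippable:

- ``long``: one ``edges_<scan_id>.csv`` per scan with columns
  ``i, j, count, fa, ndi, odi`` (1-based node indices, i < j, present
  edges only), plus ``nodes.csv`` (index, label) and ``metadata.csv``.
- ``matrix``: four full matrices per scan
  (``counts|fa|ndi|odi_<scan_id>.csv``) with node labels as the first
  row and column, plus ``metadata.csv``.

All files are comma-separated UTF-8 with a mandatory header row.
Readers validate the domain invariants on load (symmetry to 1e-9,
microstructure in [0, 1], non-negative counts) and name the offending
edge or row in errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from neonet.build import WeightedNetwork
from neonet.cohort import MultiWeightConnectome, ScanRecord

_META_COLS = [
    "subject_id", "scan_id", "ga_birth", "pma_scan",
    "sex", "sga", "resp_support", "nec", "twin",
]


def write_cohort(
    cohort: Sequence[Tuple[ScanRecord, MultiWeightConnectome]],
    out_dir: Path,
    dialect: str = "long",
) -> None:
    """Write metadata plus per-scan connectomes in the chosen dialect."""
    if dialect not in ("long", "matrix"):
        raise ValueError("dialect must be 'long' or 'matrix'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [{c: getattr(rec, c) for c in _META_COLS} for rec, _ in cohort]
    )
    meta.to_csv(out / "metadata.csv", index=False)

    labels = cohort[0][1].node_labels
    pd.DataFrame({"index": range(1, len(labels) + 1), "label": labels}).to_csv(
        out / "nodes.csv", index=False
    )
    for rec, conn in cohort:
        if dialect == "long":
            iu, ju = np.nonzero(np.triu(conn.counts, 1))
            pd.DataFrame(
                {
                    "i": iu + 1,  # 1-based in user-facing files
                    "j": ju + 1,
                    "count": conn.counts[iu, ju],
                    "fa": conn.fa[iu, ju],
                    "ndi": conn.ndi[iu, ju],
                    "odi": conn.odi[iu, ju],
                }
            ).to_csv(out / f"edges_{rec.scan_id}.csv", index=False)
        else:
            for name in ("counts", "fa", "ndi", "odi"):
                pd.DataFrame(
                    getattr(conn, name), index=labels, columns=labels
                ).to_csv(out / f"{name}_{rec.scan_id}.csv")


def _read_records(path: Path) -> List[ScanRecord]:
    meta = pd.read_csv(path / "metadata.csv")
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata.csv missing columns: {sorted(missing)}")
    return [
        ScanRecord(
            subject_id=str(r.subject_id),
            scan_id=str(r.scan_id),
            ga_birth=float(r.ga_birth),
            pma_scan=float(r.pma_scan),
            sex=str(r.sex),
            sga=bool(r.sga),
            resp_support=bool(r.resp_support),
            nec=bool(r.nec),
            twin=bool(r.twin),
        )
        for r in meta.itertuples()
    ]


def _symmetrize(mat: np.ndarray, name: str, scan_id: str) -> np.ndarray:
    asym = np.abs(mat - mat.T)
    if asym.max() > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"scan {scan_id}: {name} asymmetric at edge ({min(i, j)}, {max(i, j)}) "
            f"by {asym[i, j]:g} (tolerance 1e-9)"
        )
    return (mat + mat.T) / 2


def read_cohort(in_dir: Path) -> List[Tuple[ScanRecord, MultiWeightConnectome]]:
    """Load a cohort directory in either dialect (auto-detected)."""
    path = Path(in_dir)
    records = _read_records(path)
    nodes = pd.read_csv(path / "nodes.csv")
    labels = tuple(nodes["label"].astype(str))
    n = len(labels)

    cohort = []
    for rec in records:
        long_file = path / f"edges_{rec.scan_id}.csv"
        if long_file.exists():
            edges = pd.read_csv(long_file, float_precision="round_trip")
            for col in ("i", "j", "count", "fa", "ndi", "odi"):
                if col not in edges.columns:
                    raise ValueError(f"{long_file.name}: missing column {col!r}")
            i = edges["i"].to_numpy(int) - 1
            j = edges["j"].to_numpy(int) - 1
            if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n) | (i >= j)):
                bad = int(np.argmax((i < 0) | (i >= n) | (j < 0) | (j >= n) | (i >= j)))
                raise ValueError(f"{long_file.name}: malformed edge at row {bad + 2}")
            mats = {}
            for name, dtype in (("count", np.int64), ("fa", float), ("ndi", float), ("odi", float)):
                mat = np.zeros((n, n), dtype=dtype)
                mat[i, j] = edges[name].to_numpy(dtype)
                mat[j, i] = mat[i, j]
                mats[name] = mat
            conn = MultiWeightConnectome(
                node_labels=labels, counts=mats["count"],
                fa=mats["fa"], ndi=mats["ndi"], odi=mats["odi"],
            )
        else:
            mats = {}
            for name in ("counts", "fa", "ndi", "odi"):
                f = path / f"{name}_{rec.scan_id}.csv"
                if not f.exists():
                    raise FileNotFoundError(f"no connectome file for scan {rec.scan_id}")
                mat = pd.read_csv(f, index_col=0).to_numpy(dtype=float)
                if mat.shape != (n, n):
                    raise ValueError(f"{f.name}: expected {n}x{n} matrix, got {mat.shape}")
                mats[name] = _symmetrize(mat, name, rec.scan_id)
            conn = MultiWeightConnectome(
                node_labels=labels,
                counts=mats["counts"].astype(np.int64),
                fa=mats["fa"], ndi=mats["ndi"], odi=mats["odi"],
            )
        cohort.append((rec, conn))
    return cohort


def write_graphml(net: WeightedNetwork, path: Path) -> None:
    """Export a weighted network as GraphML with the weight kind as a graph attribute."""
    g = nx.from_numpy_array(net.weights)
    g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w == 0])
    g.graph["weight_kind"] = net.weight_kind
    if net.node_labels is not None:
        nx.set_node_attributes(g, {k: lbl for k, lbl in enumerate(net.node_labels)}, "label")
    nx.write_graphml(g, path)


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
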