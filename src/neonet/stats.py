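"""Minimum-grid construction and edge-wise association statistics.

The cohort's common connectivity backbone (the "minimum grid") is the
intersection over scans of per-scan masks keeping the strongest 30% of
connections by streamline count.  Within that grid, each edge's weight
is associated with age at MRI or with gestational age at birth by a
partial Spearman correlation: both the predictor and the edge weights
are residualised on the clinical covariates (sex, SGA, respiratory
support, NEC, and the other age variable) with a subject-level random
intercept for repeated scans, then rank-correlated.  P-values across
the grid's edges are corrected with the Benjamini-Hochberg step-up
procedure at q = 0.05.

Residualisation notes: with repeated scans the covariate model is a
random-intercept linear mixed model fit by REML and the residuals are
marginal (observed minus fixed-effect fit); when every subject has a
single scan the model degenerates to ordinary least squares, which is
applied in one vectorised pass over all edges (numerically identical
to the per-edge fit).  The default is double residualisation (both
variables); ``method="single"`` residualises only the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from neonet.build import WeightedNetwork, build_raw_network
from neonet.cohort import MultiWeightConnectome

PREDICTORS = ("age_at_mri", "ga_birth")
COVARIATE_COLUMNS = ("sex", "sga", "resp_support", "nec")


# ---------------------------------------------------------------------------
# masks and the minimum grid

def subject_mask(
    connectome: MultiWeightConnectome, d: float = 0.3, min_streamlines: int = 5
) -> np.ndarray:
    """Boolean mask of the top round(d * M) edges by streamline count.

    Uses the same deterministic ranking (count desc, NDI desc, (i, j))
    as cost thresholding.
    """
    from neonet.normalize import threshold_network

    raw = build_raw_network(connectome, "NDI", min_streamlines)
    net = threshold_network(raw, d)
    return net.weights > 0


@dataclass(frozen=True)
class MinimumGrid:
    """Intersection of per-scan masks: the cohort's common backbone."""

    mask: np.ndarray
    n_masks: int

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.mask, 1)))

    def edge_index(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.nonzero(np.triu(self.mask, 1))


def minimum_grid(masks: Sequence[np.ndarray]) -> MinimumGrid:
    """Element-wise intersection of per-scan edge masks."""
    if len(masks) == 0:
        raise ValueError("minimum grid needs at least one mask")
    shape = masks[0].shape
    for k, m in enumerate(masks):
        if m.shape != shape:
            raise ValueError(f"mask {k} has shape {m.shape}, expected {shape} (node-set mismatch)")
    grid = np.logical_and.reduce(np.asarray(masks))
    if not grid.any():
        warnings.warn("minimum grid is empty: no connection is common to all scans")
    return MinimumGrid(mask=grid, n_masks=len(masks))


# ---------------------------------------------------------------------------
# covariate control

def _design_matrix(covariates: Optional[pd.DataFrame]) -> Tuple[np.ndarray, List[str]]:
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return None, []
    cov = pd.DataFrame(covariates).copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "M").astype(float)  # F=0, M=1
    # a constant covariate carries no information beyond the intercept and
    # would make the design singular (e.g. no NEC case in a small cohort)
    keep = [c for c in cov.columns if cov[c].nunique() > 1]
    cov = cov[keep]
    if cov.shape[1] == 0:
        return None, []
    x = cov.to_numpy(dtype=float)
    return x, list(cov.columns)


def _check_rank(x: np.ndarray, names: List[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify an offending column by leave-one-out rank
        for k in range(x.shape[1]):
            if np.linalg.matrix_rank(np.delete(x, k, axis=1)) == rank:
                label = names[k - 1] if k >= 1 and k - 1 < len(names) else f"column {k}"
                raise ValueError(f"covariate matrix is rank deficient; collinear column: {label}")
        raise ValueError("covariate matrix is rank deficient")


def lme_residualize(
    values: np.ndarray,
    covariates: Optional[pd.DataFrame],
    subject_ids: Optional[Sequence] = None,
) -> np.ndarray:
    """Marginal residuals of a random-intercept covariate model.

    Fits ``values ~ 1 + covariates`` with a subject-level random
    intercept by REML and returns observed minus the fixed-effect fit.
    When every subject contributes a single scan the model degenerates
    to OLS (the random intercept is unidentifiable), which is what is
    fit in that case.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    cov_x, names = _design_matrix(covariates)
    x = np.ones((n, 1)) if cov_x is None else np.column_stack([np.ones(n), cov_x])
    if n < x.shape[1] + 3:
        raise ValueError(
            f"need at least {x.shape[1] + 3} scans for {x.shape[1]} fixed-effect "
            f"parameters, got {n}"
        )
    _check_rank(x, names)

    has_repeats = subject_ids is not None and len(set(subject_ids)) < n
    if not has_repeats:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return y - x @ beta

    result = _fit_mixed(y, x, np.asarray(subject_ids))
    return y - x @ result.fe_params


def _fit_mixed(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are expected under the null
        result = MixedLM(y, x, groups=groups).fit(reml=True)
    if not np.all(np.isfinite(result.fe_params)):
        raise RuntimeError("mixed-model fit did not converge to finite fixed effects")
    return result


def lme_variance_components(
    values: np.ndarray,
    covariates: Optional[pd.DataFrame],
    subject_ids: Sequence,
) -> Tuple[float, float]:
    """(subject-intercept variance, residual variance) of the REML fit."""
    y = np.asarray(values, dtype=float)
    cov_x, _ = _design_matrix(covariates)
    x = np.ones((y.size, 1)) if cov_x is None else np.column_stack([np.ones(y.size), cov_x])
    result = _fit_mixed(y, x, np.asarray(subject_ids))
    return float(np.asarray(result.cov_re)[0, 0]), float(result.scale)


def residualize_matrix(
    values: np.ndarray,
    covariates: Optional[pd.DataFrame],
    subject_ids: Optional[Sequence] = None,
) -> np.ndarray:
    """Column-wise :func:`lme_residualize` for an (n_scans, n_vars) matrix.

    Without repeated scans all columns share one OLS projection and are
    residualised in a single matrix product; with repeats each column
    gets its own mixed-model fit.
    """
    y = np.asarray(values, dtype=float)
    has_repeats = subject_ids is not None and len(set(subject_ids)) < y.shape[0]
    if not has_repeats:
        n = y.shape[0]
        cov_x, names = _design_matrix(covariates)
        x = np.ones((n, 1)) if cov_x is None else np.column_stack([np.ones(n), cov_x])
        _check_rank(x, names)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return y - x @ beta
    return np.column_stack(
        [lme_residualize(y[:, k], covariates, subject_ids) for k in range(y.shape[1])]
    )


# ---------------------------------------------------------------------------
# correlation and multiplicity

def _spearman_t(
    rx: np.ndarray, ry: np.ndarray, df: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided t-approximation p, column-wise.

    ``ry`` is (n, k); ``rx`` is (n,).  ``df`` defaults to n - 2 (the
    plain Spearman case, matching scipy.stats.spearmanr); partial
    correlations on residuals must pass n - 2 - k for k partialled
    covariates, the standard partial-correlation degrees of freedom.
    """
    n = rx.size
    xr = sps.rankdata(rx)
    yr = sps.rankdata(ry, axis=0)
    xr = xr - xr.mean()
    yr = yr - yr.mean(axis=0)
    denom = np.sqrt((xr**2).sum() * (yr**2).sum(axis=0))
    if np.any(denom == 0):
        raise ValueError("constant residual vector: Spearman correlation undefined")
    rho = (xr @ yr) / denom
    rho = np.clip(rho, -1.0, 1.0)
    if df is None:
        df = n - 2
    if df < 1:
        raise ValueError("not enough scans for the covariate set (df < 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2 * sps.t.sf(np.abs(t), df))
    return rho, p


def _partial_df(n: int, covariates: Optional[pd.DataFrame]) -> Optional[int]:
    if covariates is None:
        return None
    cov_x, _ = _design_matrix(covariates)
    k = 0 if cov_x is None else cov_x.shape[1]
    return n - 2 - k


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    subject_ids: Optional[Sequence] = None,
    method: str = "double",
    n_permutations: Optional[int] = None,
    seed: int = 0,
) -> Tuple[float, float]:
    """Partial Spearman correlation with mixed-model covariate control.

    Both variables (or only ``y`` with ``method="single"``) are
    residualised on the covariates via :func:`lme_residualize`; the
    residuals are then rank-correlated.  The p-value uses the t
    approximation by default, or a seeded permutation of the predictor
    residuals when ``n_permutations`` is given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("partial Spearman needs at least 5 scans")
    if method not in ("double", "single"):
        raise ValueError("method must be 'double' or 'single'")
    if covariates is not None:
        ry = lme_residualize(y, covariates, subject_ids)
        rx = lme_residualize(x, covariates, subject_ids) if method == "double" else x
    else:
        rx, ry = x, y
    rho, p = _spearman_t(rx, ry[:, None], df=_partial_df(x.size, covariates))
    rho_val, p_val = float(rho[0]), float(p[0])
    if n_permutations:
        rng = np.random.default_rng(seed)
        perm_rho = np.empty(n_permutations)
        for b in range(n_permutations):
            perm_rho[b] = _spearman_t(rng.permutation(rx), ry[:, None])[0][0]
        p_val = (1 + np.count_nonzero(np.abs(perm_rho) >= abs(rho_val))) / (n_permutations + 1)
    return rho_val, p_val


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection mask and adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_values


# ---------------------------------------------------------------------------
# edge-wise association

@dataclass(frozen=True)
class EdgeStatTable:
    """Per-edge partial correlations inside a minimum grid."""

    table: pd.DataFrame  # columns: i, j, rho, p, q, significant
    predictor: str
    weight_kind: str
    q: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def covariates_for(predictor: str, metadata: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect covariate set for one analysis direction.

    Assessing maturation (age at MRI) controls for GA at birth and the
    clinical covariates; assessing prematurity (GA at birth) swaps in
    age at MRI instead.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    other = "ga_birth" if predictor == "age_at_mri" else "pma_scan"
    return metadata[list(COVARIATE_COLUMNS) + [other]]


def predictor_values(predictor: str, metadata: pd.DataFrame) -> np.ndarray:
    col = "pma_scan" if predictor == "age_at_mri" else "ga_birth"
    return metadata[col].to_numpy(dtype=float)


def edge_weight_panel(
    cohort: Sequence[Tuple],
    grid: MinimumGrid,
    weight_kind: str,
    relative: bool = False,
    relative_density: float = 0.3,
    min_streamlines: int = 5,
) -> np.ndarray:
    """(n_scans, n_grid_edges) weight matrix for the grid's edges.

    ``relative=True`` thresholds each scan at ``relative_density`` and
    normalises the retained weights to unit sum before extraction, so
    the panel holds rFA/rNDI/r(1-ODI)-style relative weights.
    """
    from neonet.normalize import normalize_weights, threshold_network

    gi, gj = grid.edge_index()
    rows = []
    offending = []
    for rec, conn in cohort:
        net = build_raw_network(conn, weight_kind, min_streamlines)
        if relative:
            net = normalize_weights(threshold_network(net, relative_density))
        vals = net.weights[gi, gj]
        if np.any(vals <= 0):
            offending.append(rec.scan_id)
        rows.append(vals)
    if offending:
        raise ValueError(
            "scans missing weights on minimum-grid edges: " + ", ".join(offending)
        )
    return np.asarray(rows)


def edgewise_association(
    grid: MinimumGrid,
    panel: np.ndarray,
    predictor: str,
    metadata: pd.DataFrame,
    weight_kind: str = "NDI",
    q: float = 0.05,
    method: str = "double",
) -> EdgeStatTable:
    """Partial Spearman per grid edge, BH-FDR across exactly those edges.

    ``panel`` is the (n_scans, n_grid_edges) weight matrix (see
    :func:`edge_weight_panel`), row order matching ``metadata``.
    """
    if grid.n_edges == 0:
        raise ValueError("minimum grid is empty")
    if panel.shape != (len(metadata), grid.n_edges):
        raise ValueError(
            f"panel shape {panel.shape} does not match "
            f"({len(metadata)} scans, {grid.n_edges} grid edges)"
        )
    covs = covariates_for(predictor, metadata)
    x = predictor_values(predictor, metadata)
    subject_ids = metadata["subject_id"].to_numpy()

    rx = lme_residualize(x, covs, subject_ids) if method == "double" else x
    ry = residualize_matrix(panel, covs, subject_ids)
    rho, p = _spearman_t(rx, ry, df=_partial_df(len(metadata), covs))
    reject, q_values = fdr_bh(p, q=q)

    gi, gj = grid.edge_index()
    table = pd.DataFrame(
        {
            "i": gi,
            "j": gj,
            "rho": rho,
            "p": p,
            "q": q_values,
            "significant": reject,
        }
    )
    return EdgeStatTable(table=table, predictor=predictor, weight_kind=weight_kind, q=q)


def fdr_calibration_study(
    n_replicates: int = 200,
    n_scans: int = 65,
    n_signal: int = 100,
    n_null: int = 400,
    q: float = 0.05,
    seed: int = 7,
) -> Tuple[float, float]:
    """Empirical false-discovery and power of the edge-wise procedure.

    Simulates ``n_replicates`` cohorts with known signal and null edges
    (see :func:`neonet.cohort.simulate_edge_panel`), runs the full
    edge-wise association with BH correction on each, and returns
    (mean false-discovery proportion, mean power) across replicates.
    """
    from neonet.cohort import simulate_edge_panel

    n_nodes_needed = int(np.ceil((1 + np.sqrt(1 + 8 * (n_signal + n_null))) / 2))
    n = max(91, n_nodes_needed)
    iu, ju = np.triu_indices(n, 1)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[: n_signal + n_null], ju[: n_signal + n_null]] = True
    mask |= mask.T
    grid = MinimumGrid(mask=mask, n_masks=n_scans)

    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    fdps, powers = [], []
    for s in rep_seeds:
        meta, panel, is_signal = simulate_edge_panel(
            n_scans=n_scans, n_signal=n_signal, n_null=n_null, seed=int(s)
        )
        result = edgewise_association(grid, panel, "ga_birth", meta, q=q)
        rej = result.table["significant"].to_numpy()
        n_rej = rej.sum()
        fdps.append((rej & ~is_signal).sum() / max(n_rej, 1))
        powers.append((rej & is_signal).sum() / max(is_signal.sum(), 1))
    return float(np.mean(fdps)), float(np.mean(powers))
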