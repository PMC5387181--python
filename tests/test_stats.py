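"""Minimum grid, mixed-model residualisation, partial Spearman, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neonet.cohort import simulate_edge_panel
from neonet.stats import (
    MinimumGrid,
    edgewise_association,
    fdr_bh,
    lme_residualize,
    lme_variance_components,
    minimum_grid,
    partial_spearman,
    subject_mask,
)
from oracles import brute_fdr_bh


def mask_from_edges(n, edges):
    m = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        m[i, j] = m[j, i] = True
    return m


def test_subject_mask_edge_count(default_cohort):
    """The 0.3-density mask keeps round(0.3 * 4095) = 1229 edges."""
    _, conn = default_cohort[0]
    mask = subject_mask(conn, d=0.3)
    assert np.count_nonzero(np.triu(mask, 1)) == 1229
    assert np.array_equal(mask, mask.T)
    assert not mask.diagonal().any()


def test_minimum_grid_is_intersection():
    a = mask_from_edges(5, [(0, 1), (0, 2), (0, 3)])
    b = mask_from_edges(5, [(0, 2), (0, 3), (1, 4)])
    grid = minimum_grid([a, b])
    assert grid.n_edges == 2
    gi, gj = grid.edge_index()
    assert set(zip(gi, gj)) == {(0, 2), (0, 3)}
    same = minimum_grid([a, a])
    assert np.array_equal(same.mask, a)


def test_minimum_grid_empty_warns_and_shape_mismatch_errors():
    a = mask_from_edges(5, [(0, 1)])
    empty = np.zeros((5, 5), dtype=bool)
    with pytest.warns(UserWarning, match="empty"):
        grid = minimum_grid([a, empty])
    assert grid.n_edges == 0
    with pytest.raises(ValueError, match="node-set"):
        minimum_grid([a, np.zeros((4, 4), dtype=bool)])


def test_residuals_demean_without_covariates():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
    res = lme_residualize(vals, None, subject_ids=list("abcde"))
    assert res == pytest.approx(vals - vals.mean())


def test_perfect_covariate_gives_zero_residuals():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=12)
    covs = pd.DataFrame({"c": vals})
    res = lme_residualize(vals, covs, subject_ids=[str(k) for k in range(12)])
    assert np.allclose(res, 0.0, atol=1e-10)


def test_collinear_covariates_rejected():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=10)
    c = rng.normal(size=10)
    covs = pd.DataFrame({"a": c, "b": 2 * c})
    with pytest.raises(ValueError, match="rank deficient"):
        lme_residualize(vals, covs, subject_ids=[str(k) for k in range(10)])


def test_random_intercept_variance_recovery():
    """REML recovers the intercept variance of a known generating model."""
    true_tau2, true_sigma2 = 0.5, 1.0
    n_sub, n_rep = 200, 2
    ests = []
    rng = np.random.default_rng(42)
    for _ in range(100):
        u = rng.normal(0, np.sqrt(true_tau2), n_sub)
        y = np.repeat(u, n_rep) + rng.normal(0, np.sqrt(true_sigma2), n_sub * n_rep)
        sid = np.repeat(np.arange(n_sub), n_rep)
        tau2, sigma2 = lme_variance_components(y, None, sid)
        ests.append(tau2)
    assert abs(np.mean(ests) - true_tau2) / true_tau2 < 0.15


def test_partial_spearman_monotone_extremes():
    x = np.arange(10, dtype=float)
    rho, p = partial_spearman(x, np.exp(x))
    assert rho == pytest.approx(1.0)
    rho, p = partial_spearman(x, -(x**3))
    assert rho == pytest.approx(-1.0)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_partial_spearman_invariant_to_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    rho0, _ = partial_spearman(x, y)
    rho1, _ = partial_spearman(np.exp(x), y)
    rho2, _ = partial_spearman(x, y**3)
    assert rho1 == pytest.approx(rho0)
    assert rho2 == pytest.approx(rho0)


def test_null_rejection_rate_calibrated():
    """Independent x, y at n=65: p<0.05 rejected in 5% +/- 1% of 2000 replicates."""
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        x = rng.normal(size=65)
        y = rng.normal(size=65)
        _, p = partial_spearman(x, y)
        rejections += p < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.01)


def test_constant_vector_rejected():
    with pytest.raises(ValueError, match="constant"):
        partial_spearman(np.ones(8), np.arange(8.0))


def test_fdr_bh_step_up_examples():
    reject, qv = fdr_bh(np.array([0.001, 0.02, 0.03, 0.5]), q=0.05)
    assert list(reject) == [True, True, True, False]
    assert np.all(qv >= [0.001, 0.02, 0.03, 0.5])
    reject, _ = fdr_bh(np.ones(5), q=0.05)
    assert not reject.any()
    reject, qv = fdr_bh(np.array([0.04]), q=0.05)
    assert reject[0] and qv[0] == pytest.approx(0.04)
    with pytest.raises(ValueError):
        fdr_bh(np.array([0.1, 1.2]))


def test_fdr_bh_matches_brute_force_step_up():
    rng = np.random.default_rng(3)
    for _ in range(200):
        m = int(rng.integers(1, 7))
        p = np.round(rng.random(m), 3)
        reject, _ = fdr_bh(p, q=0.05)
        assert np.array_equal(reject, brute_fdr_bh(p, 0.05))


def test_edgewise_single_edge_grid_q_equals_p():
    meta, panel, _ = simulate_edge_panel(n_scans=30, n_signal=1, n_null=0, seed=2)
    grid = MinimumGrid(mask=mask_from_edges(91, [(0, 1)]), n_masks=30)
    res = edgewise_association(grid, panel, "ga_birth", meta)
    assert len(res.table) == 1
    assert res.table["q"].iloc[0] == pytest.approx(res.table["p"].iloc[0])


def test_edgewise_panel_shape_mismatch_errors():
    meta, panel, _ = simulate_edge_panel(n_scans=30, n_signal=2, n_null=2, seed=2)
    grid = MinimumGrid(mask=mask_from_edges(91, [(0, 1)]), n_masks=30)
    with pytest.raises(ValueError, match="panel shape"):
        edgewise_association(grid, panel, "ga_birth", meta)


def test_edgewise_detects_designed_signal_edges():
    """Signal edges dominate the significant set; rerun is identical."""
    meta, panel, is_signal = simulate_edge_panel(
        n_scans=65, n_signal=10, n_null=90, seed=11
    )
    iu, ju = np.triu_indices(91, 1)
    mask = mask_from_edges(91, list(zip(iu[:100], ju[:100])))
    grid = MinimumGrid(mask=mask, n_masks=65)
    res = edgewise_association(grid, panel, "ga_birth", meta)
    rej = res.table["significant"].to_numpy()
    assert rej[is_signal].mean() > 0.5
    res2 = edgewise_association(grid, panel, "ga_birth", meta)
    pd.testing.assert_frame_equal(res.table, res2.table)


def test_permutation_p_agrees_with_t_approximation():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    _, p_t = partial_spearman(x, y)
    _, p_perm = partial_spearman(x, y, n_permutations=999, seed=1)
    assert p_perm == pytest.approx(p_t, abs=0.02)
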