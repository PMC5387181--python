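"""Synthetic cohort generator: structure, determinism, latent design."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neonet.build import build_raw_network
from neonet.cohort import (
    CohortConfig,
    MultiWeightConnectome,
    ScanRecord,
    generate_cohort,
    latent_design,
    records_frame,
    simulate_edge_panel,
)
from neonet.metrics import network_density


def test_cohort_size_and_repeat_structure(default_cohort):
    """65 subjects plus 8 second scans yield 73 scan entries with shared subject ids."""
    assert len(default_cohort) == 73
    meta = records_frame(default_cohort)
    assert meta["scan_id"].is_unique
    counts = meta.groupby("subject_id").size()
    assert (counts == 2).sum() == 8
    assert counts.sum() == 73
    # repeated scans: same subject metadata, later scan age
    for sid in counts[counts == 2].index:
        pair = meta[meta["subject_id"] == sid].sort_values("scan_id")
        assert pair["ga_birth"].nunique() == 1
        assert pair["pma_scan"].iloc[1] > pair["pma_scan"].iloc[0]


def test_single_subject_cohort_satisfies_invariants():
    cohort = generate_cohort(CohortConfig(n_subjects=1, n_repeat_scans=0, seed=3))
    assert len(cohort) == 1
    rec, conn = cohort[0]
    assert conn.counts.shape == (91, 91)
    assert np.array_equal(conn.counts, conn.counts.T)
    assert np.all(np.diagonal(conn.counts) == 0)
    present = conn.counts > 0
    for mat in (conn.fa, conn.ndi, conn.odi):
        assert mat[present].min() >= 0 and mat[present].max() <= 1
    assert rec.pma_scan >= rec.ga_birth


def test_determinism_same_seed_identical_output():
    cfg = CohortConfig(n_subjects=6, n_repeat_scans=2, node_count=30, seed=11)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for (ra, ca), (rb, cb) in zip(a, b):
        assert ra == rb
        assert np.array_equal(ca.counts, cb.counts)
        assert np.array_equal(ca.ndi, cb.ndi)


def test_raw_density_floor_and_age_trend(default_cohort, default_metadata):
    """Raw (>=5-streamline) density is >= 0.5 everywhere and falls with PMA."""
    dens = [
        network_density(build_raw_network(conn, "BINARY")) for _, conn in default_cohort
    ]
    assert min(dens) >= 0.50
    rho, p = sps.spearmanr(dens, default_metadata["pma_scan"])
    assert rho < 0 and p < 0.01


def test_microstructure_age_trends(default_cohort, default_metadata):
    """Median FA/NDI rise with PMA; median coherence 1-ODI falls."""
    med = {k: [] for k in ("FA", "NDI", "ODI_C")}
    for _, conn in default_cohort:
        for kind in med:
            net = build_raw_network(conn, kind)
            med[kind].append(np.median(net.edge_values()))
    pma = default_metadata["pma_scan"]
    assert sps.spearmanr(med["FA"], pma).statistic > 0
    assert sps.spearmanr(med["NDI"], pma).statistic > 0
    assert sps.spearmanr(med["ODI_C"], pma).statistic < 0


def test_latent_design_partition_and_core_count():
    cfg = CohortConfig(seed=2, core_fraction_of_edges=0.1)
    design = latent_design(cfg)
    assert len(design) == 91 * 90 // 2 == 4095
    # round-half-up of 0.1 * 4095 = 409.5
    assert design["core"].sum() == 410
    # every edge appears exactly once across core/local
    assert (design["core"] ^ design["ga_effect"]).all()
    # deterministic per seed
    assert design.equals(latent_design(cfg))


def test_latent_design_tiny_core_fraction():
    design = latent_design(CohortConfig(seed=2, core_fraction_of_edges=1e-9))
    assert design["core"].sum() == 0


def test_config_validation_errors():
    with pytest.raises(ValueError, match="cost-sweep"):
        CohortConfig(backbone_density=0.4).validate()
    with pytest.raises(ValueError, match="core_fraction"):
        CohortConfig(core_fraction_of_edges=1.5).validate()
    with pytest.raises(ValueError, match="n_repeat_scans"):
        CohortConfig(n_subjects=5, n_repeat_scans=6).validate()


def test_scan_record_rejects_impossible_ages():
    with pytest.raises(ValueError, match="pma_scan"):
        ScanRecord(
            subject_id="s", scan_id="s_1", ga_birth=40.0, pma_scan=30.0,
            sex="F", sga=False, resp_support=False, nec=False,
        )


def test_edge_panel_signal_and_null_structure():
    meta, panel, is_signal = simulate_edge_panel(
        n_scans=40, n_signal=5, n_null=10, seed=4
    )
    assert panel.shape == (40, 15)
    assert is_signal.sum() == 5
    ga = meta["ga_birth"]
    # designed signal columns correlate with GA at birth, nulls do not systematically
    sig_rho = [sps.spearmanr(ga, panel[:, k]).statistic for k in range(5)]
    assert min(sig_rho) > 0.2
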