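"""Seeded synthetic cohorts of multi-weight structural connectomes.

The generator emulates the statistical structure of a neonatal
preterm/term cohort scanned between roughly 25 and 46 weeks
post-menstrual age (PMA): a 91-region parcellation, raw network density
in the 0.55-0.88 range that *decreases* with age at scan, edge-level FA
and NDI that *increase* with age while fibre coherence (1-ODI)
decreases, clinical covariates with realistic prevalences, and a small
set of subjects scanned twice.  A latent edge design partitions all
possible edges into a high-strength "core" and the remaining "local"
edges; gestational age at birth (GA) modulates NDI only on local edges,
so that downstream core/local and edge-wise analyses have a known truth
table to recover.

Every draw comes from one :class:`numpy.random.SeedSequence` derived
from ``config.seed``, so a cohort is a pure function of its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

N_NODES_DEFAULT = 91

# Cohort composition: prevalences follow the clinical characteristics of
# a 65-infant neonatal cohort (respiratory support 22/65, NEC 7/65,
# SGA 19/65, twins 18/65; GA-at-birth strata 6/15/31/13 across
# extremely-preterm/very-preterm/preterm/term).
GA_STRATA = ((24.0, 28.0, 6), (28.0, 32.0, 15), (32.0, 37.0, 31), (37.0, 42.0, 13))
P_RESP_SUPPORT = 22 / 65
P_NEC = 7 / 65
P_SGA = 19 / 65
P_TWIN = 18 / 65


@dataclass(frozen=True)
class ScanRecord:
    """Metadata for one MRI session.

    ``subject_id`` is shared across a subject's repeated scans while
    ``scan_id`` is unique per session.  Ages are decimal weeks.
    """

    subject_id: str
    scan_id: str
    ga_birth: float
    pma_scan: float
    sex: str  # "M" | "F"
    sga: bool
    resp_support: bool
    nec: bool
    twin: bool = False

    def __post_init__(self) -> None:
        if self.pma_scan < self.ga_birth:
            raise ValueError(
                f"scan {self.scan_id}: pma_scan ({self.pma_scan}) < ga_birth ({self.ga_birth})"
            )
        if self.sex not in ("M", "F"):
            raise ValueError(f"scan {self.scan_id}: sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class MultiWeightConnectome:
    """Streamline counts plus per-edge microstructure medians.

    ``counts`` is a symmetric non-negative integer matrix with zero
    diagonal; ``fa``/``ndi``/``odi`` hold the per-edge median
    microstructure values in [0, 1], defined only where ``counts > 0``
    (zero elsewhere by convention).
    """

    node_labels: Tuple[str, ...]
    counts: np.ndarray
    fa: np.ndarray
    ndi: np.ndarray
    odi: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        for name in ("counts", "fa", "ndi", "odi"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if not np.allclose(m, m.T):
                bad = np.argwhere(~np.isclose(m, m.T))[0]
                raise ValueError(f"{name} asymmetric at edge ({bad[0]}, {bad[1]})")
            if np.any(np.diagonal(m) != 0):
                raise ValueError(f"{name} has nonzero diagonal entries")
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be non-negative")
        present = self.counts > 0
        for name in ("fa", "ndi", "odi"):
            m = getattr(self, name)
            vals = m[present]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"{name} values outside [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Age and GA slopes are per week on the microstructure scale (so a
    0.012/week NDI slope spans ~0.25 units over the 25-46 week scan
    window).  ``ga_effect_ndi`` applies only to edges flagged "local" in
    the latent design; "core" edges carry no GA effect.
    """

    n_subjects: int = 65
    n_repeat_scans: int = 8
    node_count: int = N_NODES_DEFAULT
    target_raw_density_range: Tuple[float, float] = (0.55, 0.88)
    backbone_density: float = 0.54
    density_age_slope: float = -0.17  # logit of non-backbone edge presence, per week
    fa_age_slope: float = 0.008
    ndi_age_slope: float = 0.012
    odi_age_slope: float = 0.006  # ODI (dispersion) rises, so coherence 1-ODI falls
    ga_effect_ndi: float = 0.005
    core_fraction_of_edges: float = 0.1
    edge_noise_sd: float = 0.03
    # small additive covariate effects on NDI so covariate control is testable
    cov_effects_ndi: Tuple[float, float, float, float] = (0.008, -0.010, -0.008, -0.012)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.n_repeat_scans <= self.n_subjects:
            raise ValueError("n_repeat_scans must be in [0, n_subjects]")
        if self.node_count < 2:
            raise ValueError("node_count must be >= 2")
        if not 0 < self.core_fraction_of_edges < 1:
            raise ValueError("core_fraction_of_edges must be in (0, 1)")
        if self.backbone_density < 0.50:
            raise ValueError(
                "backbone_density < 0.50 would allow raw densities below 0.50, "
                "breaking the cost-sweep precondition (density grid up to 0.50 "
                "requires every raw network to have density >= 0.50)"
            )
        for name in (
            "density_age_slope", "fa_age_slope", "ndi_age_slope", "odi_age_slope",
            "ga_effect_ndi", "edge_noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _n_edges(n: int) -> int:
    return n * (n - 1) // 2


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def latent_design(config: CohortConfig) -> pd.DataFrame:
    """Edge-level ground truth for a cohort: the test oracle.

    Returns one row per possible unordered edge (i < j) with columns:

    - ``strength``: latent long-tailed mean streamline count,
    - ``backbone``: edge always present (guarantees raw density >=
      ``backbone_density``),
    - ``core``: top ``core_fraction_of_edges`` of edges by strength —
      spared from the GA-at-birth effect,
    - ``ga_effect``: the complement of ``core`` (the "local" edges
      whose NDI rises with GA at birth),
    - ``fa0``/``ndi0``/``odi0``: per-edge baseline microstructure,
    - per-weight age slopes (constant columns, for convenience).

    Deterministic per ``config.seed``; the core count uses round-half-up
    of ``core_fraction_of_edges * total``.
    """
    config.validate()
    n = config.node_count
    m = _n_edges(n)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    iu, ju = np.triu_indices(n, 1)
    strength = rng.lognormal(mean=3.0, sigma=1.3, size=m)
    order = np.argsort(-strength, kind="stable")
    n_core = _round_half_up(config.core_fraction_of_edges * m)
    n_backbone = _round_half_up(config.backbone_density * m)
    core = np.zeros(m, dtype=bool)
    core[order[:n_core]] = True
    backbone = np.zeros(m, dtype=bool)
    backbone[order[:n_backbone]] = True

    # core tracts are the strong, early-maturing pathways: elevated baseline
    # NDI, which is what lets the relative-weight core/local dissociation
    # appear once weights are normalised to unit sum
    ndi0 = rng.uniform(0.20, 0.50, size=m)
    ndi0[core] = rng.uniform(0.45, 0.65, size=int(core.sum()))
    design = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "strength": strength,
            "backbone": backbone,
            "core": core,
            "ga_effect": ~core,
            "fa0": rng.uniform(0.15, 0.45, size=m),
            "ndi0": ndi0,
            "odi0": rng.uniform(0.15, 0.45, size=m),
        }
    )
    design["fa_age_slope"] = config.fa_age_slope
    design["ndi_age_slope"] = config.ndi_age_slope
    design["odi_age_slope"] = config.odi_age_slope
    design["ndi_ga_slope"] = np.where(design["ga_effect"], config.ga_effect_ndi, 0.0)
    return design


def _sample_records(config: CohortConfig, rng: np.random.Generator) -> List[ScanRecord]:
    """Draw subject metadata and the repeated-scan structure."""
    n = config.n_subjects
    weights = np.array([s[2] for s in GA_STRATA], dtype=float)
    strata = rng.choice(len(GA_STRATA), size=n, p=weights / weights.sum())
    ga = np.array([rng.uniform(GA_STRATA[s][0], GA_STRATA[s][1]) for s in strata])
    pma = np.array([rng.uniform(max(g + 0.5, 25.0), 45.0) for g in ga])
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    sga = rng.random(n) < P_SGA
    resp = rng.random(n) < P_RESP_SUPPORT
    nec = rng.random(n) < P_NEC
    twin = rng.random(n) < P_TWIN

    records = [
        ScanRecord(
            subject_id=f"sub-{k + 1:03d}",
            scan_id=f"sub-{k + 1:03d}_ses-1",
            ga_birth=round(float(ga[k]), 2),
            pma_scan=round(float(pma[k]), 2),
            sex=str(sex[k]),
            sga=bool(sga[k]),
            resp_support=bool(resp[k]),
            nec=bool(nec[k]),
            twin=bool(twin[k]),
        )
        for k in range(n)
    ]

    # second scans ~3.5-8.7 weeks later, never past 46 weeks PMA;
    # prefer the subjects scanned earliest so the follow-up fits
    if config.n_repeat_scans:
        eligible = np.argsort(pma)[: max(config.n_repeat_scans, 1)]
        for k in eligible[: config.n_repeat_scans]:
            delay = rng.uniform(3.5, 8.7)
            rec = records[k]
            records.append(
                replace(
                    rec,
                    scan_id=f"{rec.subject_id}_ses-2",
                    pma_scan=round(min(rec.pma_scan + delay, 45.9), 2),
                )
            )
    return records


def _scan_connectome(
    config: CohortConfig,
    design: pd.DataFrame,
    record: ScanRecord,
    rng: np.random.Generator,
    node_labels: Tuple[str, ...],
) -> MultiWeightConnectome:
    n = config.node_count
    m = len(design)
    pma_c = record.pma_scan - 35.5
    ga_c = record.ga_birth - 33.3

    backbone = design["backbone"].to_numpy()
    strength = design["strength"].to_numpy()

    # edge presence: backbone always on; other edges via an age-dependent
    # logistic probability so density falls with PMA but never below backbone
    p_extra = expit(-0.35 + config.density_age_slope * pma_c)
    present = backbone | (rng.random(m) < p_extra)

    # counts: shifted negative binomials; the backbone floor of 5 means only
    # non-backbone edges exercise the >=5-streamline raw filter
    counts = np.zeros(m, dtype=np.int64)
    nb = backbone
    mu_b = np.maximum(strength[nb], 1.0)
    r_b = 8.0
    counts[nb] = 5 + rng.negative_binomial(r_b, r_b / (r_b + mu_b))
    ex = present & ~backbone
    if ex.any():
        mu_e = np.minimum(np.maximum(strength[ex], 2.0), 20.0)
        r_e = 3.0
        counts[ex] = 1 + rng.negative_binomial(r_e, r_e / (r_e + mu_e))

    sd = config.edge_noise_sd
    b_sex, b_sga, b_resp, b_nec = config.cov_effects_ndi
    cov_shift = (
        b_sex * (record.sex == "M")
        + b_sga * record.sga
        + b_resp * record.resp_support
        + b_nec * record.nec
    )
    fa = design["fa0"].to_numpy() + config.fa_age_slope * pma_c + rng.normal(0, sd, m)
    ndi = (
        design["ndi0"].to_numpy()
        + config.ndi_age_slope * pma_c
        + design["ndi_ga_slope"].to_numpy() * ga_c
        + cov_shift
        + rng.normal(0, sd, m)
    )
    odi = design["odi0"].to_numpy() + config.odi_age_slope * pma_c + rng.normal(0, sd, m)
    # keep microstructure strictly inside (0, 1) so coherence weights stay positive
    fa, ndi, odi = (np.clip(v, 1e-3, 1 - 1e-3) for v in (fa, ndi, odi))

    iu = design["i"].to_numpy()
    ju = design["j"].to_numpy()

    def to_matrix(vec: np.ndarray, dtype) -> np.ndarray:
        mat = np.zeros((n, n), dtype=dtype)
        mat[iu, ju] = vec
        mat[ju, iu] = vec
        return mat

    absent = counts == 0
    fa[absent] = 0.0
    ndi[absent] = 0.0
    odi[absent] = 0.0
    return MultiWeightConnectome(
        node_labels=node_labels,
        counts=to_matrix(counts, np.int64),
        fa=to_matrix(fa, float),
        ndi=to_matrix(ndi, float),
        odi=to_matrix(odi, float),
    )


def default_node_labels(n: int = N_NODES_DEFAULT) -> Tuple[str, ...]:
    """Opaque region labels for an n-node parcellation."""
    return tuple(f"ROI{k + 1:03d}" for k in range(n))


def generate_cohort(
    config: CohortConfig,
) -> List[Tuple[ScanRecord, MultiWeightConnectome]]:
    """Generate ``n_subjects + n_repeat_scans`` scans, deterministically per seed.

    Raw (>=5-streamline) density of every connectome is >= 0.50 by
    construction (the always-present backbone), so the full 0.05-0.50
    cost sweep is feasible for every scan; the generator re-checks this
    and raises if a configuration violates it.
    """
    config.validate()
    design = latent_design(config)
    ss = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(ss)
    labels = default_node_labels(config.node_count)

    records = _sample_records(config, rng)
    cohort = []
    m = _n_edges(config.node_count)
    for rec in records:
        conn = _scan_connectome(config, design, rec, rng, labels)
        raw_density = np.count_nonzero(conn.counts[np.triu_indices(config.node_count, 1)] >= 5) / m
        if raw_density < 0.50:
            raise ValueError(
                f"scan {rec.scan_id}: raw network density {raw_density:.3f} < 0.50 "
                "violates the cost-sweep precondition (densities up to 0.50 must be "
                "reachable for every scan); raise backbone_density"
            )
        cohort.append((rec, conn))
    return cohort


def simulate_edge_panel(
    n_scans: int = 65,
    n_signal: int = 100,
    n_null: int = 400,
    ga_effect: float = 0.005,
    edge_noise_sd: float = 0.03,
    cov_effects: Tuple[float, float, float, float] = (0.008, -0.010, -0.008, -0.012),
    seed: int = 0,
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Edge-weight panel with known signal and null edges.

    A calibration harness for the edge-wise statistics: draws
    ``n_scans`` single-scan subjects with the cohort's metadata
    distribution and an (n_scans, n_signal + n_null) weight panel in
    which the first ``n_signal`` columns carry a GA-at-birth slope of
    ``ga_effect`` per week and the rest are null.  All columns carry
    the covariate effects, so covariate control is exercised.  Returns
    (metadata, panel, is_signal).
    """
    cfg = CohortConfig(n_subjects=n_scans, n_repeat_scans=0, seed=seed)
    ss = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(ss[2])
    records = _sample_records(cfg, np.random.default_rng(ss[1]))
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "scan_id": [r.scan_id for r in records],
            "ga_birth": [r.ga_birth for r in records],
            "pma_scan": [r.pma_scan for r in records],
            "sex": [r.sex for r in records],
            "sga": [r.sga for r in records],
            "resp_support": [r.resp_support for r in records],
            "nec": [r.nec for r in records],
        }
    )
    m = n_signal + n_null
    is_signal = np.zeros(m, dtype=bool)
    is_signal[:n_signal] = True
    base = rng.uniform(0.2, 0.5, size=m)
    b_sex, b_sga, b_resp, b_nec = cov_effects
    cov_shift = (
        b_sex * (meta["sex"] == "M").to_numpy(float)
        + b_sga * meta["sga"].to_numpy(float)
        + b_resp * meta["resp_support"].to_numpy(float)
        + b_nec * meta["nec"].to_numpy(float)
    )
    ga_c = meta["ga_birth"].to_numpy(float) - 33.3
    panel = (
        base[None, :]
        + cov_shift[:, None]
        + ga_effect * np.outer(ga_c, is_signal.astype(float))
        + rng.normal(0, edge_noise_sd, size=(n_scans, m))
    )
    return meta, panel, is_signal


def records_frame(cohort: List[Tuple[ScanRecord, MultiWeightConnectome]]) -> pd.DataFrame:
    """Tidy metadata table, one row per scan."""
    rows = [
        {
            "subject_id": r.subject_id,
            "scan_id": r.scan_id,
            "ga_birth": r.ga_birth,
            "pma_scan": r.pma_scan,
            "sex": r.sex,
            "sga": r.sga,
            "resp_support": r.resp_support,
            "nec": r.nec,
            "twin": r.twin,
        }
        for r, _ in cohort
    ]
    return pd.DataFrame(rows)
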