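"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates an affinity-proteomics study of ovarian-carcinoma
ascites: log-normal relative abundances over ~10^3 probes, a majority of
ascites plus a minority of plasma samples, a latent two-cluster structure in
ascites, and a minority of probes with planted survival effects that act
through *threshold exceedance* — a patient's relapse hazard is multiplied
up or down according to whether each planted protein exceeds its planted
quantile threshold.  Survival times are exponential given the per-patient
hazard; censoring is independent uniform administrative censoring calibrated
to a requested censoring fraction.

Ground truth (planted marker identities, true thresholds, latent risk
class) is returned alongside the cohort for recovery tests.  A noisy
second-platform replicate (monotone per-protein transform plus log-scale
noise) and extracellular-vesicle (EV) fixtures are generated on top of a
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_data import AbundanceMatrix, ClinicalTable, CohortDataset

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "EvSimulation",
    "generate_cohort",
    "generate_second_platform",
    "calibrate_rank_noise",
    "generate_ev_tables",
]


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 70 ascites patients plus 30 plasma
    samples, a 1,305-probe panel, a minority of planted adverse/favorable
    markers, a median RFS of 18 months (relapse typically within two
    years), ~30% right-censoring and two latent ascites clusters.
    """

    n_patients: int = 70
    n_proteins: int = 1305
    n_adverse: int = 12
    n_favorable: int = 12
    effect_log_hr: float = math.log(3.0)
    planted_quantile: float = 0.5
    baseline_median_rfs_months: float = 18.0
    censoring_rate: float = 0.3
    cluster_fraction: float = 0.5
    abundance_log_mean: float = 7.5
    abundance_log_sd: float = 1.0
    platform2_rank_noise: float = 0.5
    planted_separation_sd: float = 5.0
    planted_trait_mode: str = "independent"  # or "shared"
    trait_flip_rate: float = 0.05
    seed: int = 0
    # secondary structure (fixed defaults; not part of the headline contract)
    n_oc_plasma: int = 20
    n_n_plasma: int = 10
    plasma_log_shift: float = -1.0
    protein_level_log_sd: float = 1.0
    cluster_log_shift: float = 1.0
    cluster_block_fraction: float = 0.10
    rfs_cutoff_months: float = 24.0

    def __post_init__(self):
        if self.n_patients < 2 or self.n_proteins < 1:
            raise ValueError("cohort must have >= 2 patients and >= 1 protein")
        if self.n_adverse < 0 or self.n_favorable < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_adverse + self.n_favorable > self.n_proteins:
            raise ValueError("more planted proteins than proteins")
        if not 0 < self.planted_quantile < 1:
            raise ValueError("planted_quantile must be in (0,1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0,1)")
        if not 0 < self.cluster_fraction < 1:
            raise ValueError("cluster_fraction must be in (0,1)")
        if self.effect_log_hr < 0:
            raise ValueError("effect_log_hr must be >= 0")
        if self.abundance_log_sd <= 0 or self.baseline_median_rfs_months <= 0:
            raise ValueError("scales must be positive")
        if self.platform2_rank_noise < 0:
            raise ValueError("platform2_rank_noise must be >= 0")
        if self.planted_trait_mode not in ("independent", "shared"):
            raise ValueError("planted_trait_mode must be 'independent' or 'shared'")
        if not 0 <= self.trait_flip_rate < 0.5:
            raise ValueError("trait_flip_rate must be in [0, 0.5)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    adverse_ids: list
    favorable_ids: list
    true_thresholds: dict  # planted protein id -> abundance threshold
    patient_risk_class: pd.Series  # latent short/long propensity per patient
    cluster_labels: pd.Series  # ascites sample -> {0, 1}
    cluster_block_ids: list
    hazards: pd.Series  # per-patient relapse hazard (1/month)


def _uniform_censor_max(hazards: np.ndarray, target: float) -> float:
    """Upper bound c of U(0,c) censoring such that the expected censored
    fraction equals ``target`` (exact given the hazards; bisection)."""
    if target <= 0:
        return math.inf

    def frac(c):
        lc = hazards * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-6, 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological hazards
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(cfg: SyntheticConfig, patient_seed=None):
    """Generate a cohort and its ground truth; bit-identical under a seed.

    Hazard model: per patient the relapse hazard is
    ``(ln 2 / baseline_median) * exp( sum_j effect_log_hr * s_j )`` where
    ``s_j = +1`` if an adverse planted protein exceeds its planted-quantile
    threshold and ``-1`` otherwise, with the sign flipped for favorable
    proteins.  Survival times are exponential; censoring is independent
    uniform administrative censoring hitting ~``censoring_rate``.

    ``patient_seed`` (default: the config seed) drives the patient-level
    randomness only; the study design (protein baselines, planted marker
    identities, thresholds, cluster block) is a function of ``cfg.seed``
    alone, so a held-out cohort sharing the ground truth of a training
    cohort is obtained by passing a different ``patient_seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    design_ss, _ = ss.spawn(2)
    r_prot = np.random.default_rng(design_ss)
    if patient_seed is None:
        patient_seed = cfg.seed
    patient_ss = np.random.SeedSequence(entropy=patient_seed, spawn_key=(1,))
    (r_asc, r_plasma, r_surv, r_cens, r_cluster, r_trait) = [
        np.random.default_rng(s) for s in patient_ss.spawn(6)
    ]

    protein_ids = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    patient_ids = [f"PT{i:03d}" for i in range(1, cfg.n_patients + 1)]
    asc_ids = [f"ASC{i:03d}" for i in range(1, cfg.n_patients + 1)]

    mu = r_prot.normal(cfg.abundance_log_mean, cfg.protein_level_log_sd, cfg.n_proteins)

    # latent 2-cluster structure: a block of probes shifted up in cluster 1
    n_block = int(round(cfg.cluster_block_fraction * cfg.n_proteins))
    perm = r_prot.permutation(cfg.n_proteins)
    block_idx = np.sort(perm[:n_block])
    # planted markers drawn outside the cluster block so their marginal
    # distribution (hence the true threshold) is pure log-normal
    rest = perm[n_block:]
    n_planted = cfg.n_adverse + cfg.n_favorable
    if n_planted > len(rest):
        raise ValueError("not enough non-block proteins for planted effects")
    planted_idx = np.sort(rest[:n_planted])
    adverse_idx = planted_idx[: cfg.n_adverse]
    favorable_idx = planted_idx[cfg.n_adverse :]

    cluster = (r_cluster.random(cfg.n_patients) < cfg.cluster_fraction).astype(int)
    log_asc = mu[None, :] + r_asc.normal(
        0.0, cfg.abundance_log_sd, (cfg.n_patients, cfg.n_proteins)
    )
    shift = np.zeros(cfg.n_proteins)
    shift[block_idx] = cfg.cluster_log_shift
    log_asc += np.where(cluster[:, None] == 1, shift[None, :], 0.0)
    asc_values = np.exp(log_asc)

    # planted thresholds.  Planted markers carry a *bimodal* abundance: a
    # latent exceedance trait shifts each patient's level to a high or low
    # mode separated by planted_separation_sd log-sds, so that threshold
    # exceedance is a stable patient property rather than a knife-edge on a
    # unimodal distribution; the trait is drawn to exceed with probability
    # 1 - planted_quantile, and the true threshold is the inter-mode
    # midpoint.  With planted_separation_sd = 0 the markers stay unimodal
    # log-normal and the true threshold is the theoretical quantile.
    zq = norm.ppf(cfg.planted_quantile)
    thresholds = np.exp(mu + cfg.abundance_log_sd * zq)
    latent_risk = None
    if n_planted and cfg.planted_separation_sd > 0:
        sep = cfg.planted_separation_sd * cfg.abundance_log_sd
        n_exceed = int(round((1.0 - cfg.planted_quantile) * cfg.n_patients))
        trait = np.zeros((cfg.n_patients, n_planted), dtype=bool)
        if cfg.planted_trait_mode == "independent":
            for jj in range(n_planted):
                trait[r_trait.permutation(cfg.n_patients)[:n_exceed], jj] = True
        else:
            # shared mode: one latent binary risk factor; adverse markers
            # exceed their threshold for risk-positive patients, favorable
            # markers for risk-negative patients, each with a small
            # per-marker flip rate (emulates two anti-correlated marker
            # blocks tied to opposite survival outcomes)
            latent_risk = np.zeros(cfg.n_patients, dtype=bool)
            latent_risk[r_trait.permutation(cfg.n_patients)[: cfg.n_patients // 2]] = True
            flips = r_trait.random((cfg.n_patients, n_planted)) < cfg.trait_flip_rate
            base = np.empty((cfg.n_patients, n_planted), dtype=bool)
            base[:, : cfg.n_adverse] = latent_risk[:, None]
            base[:, cfg.n_adverse :] = ~latent_risk[:, None]
            trait = base ^ flips
        log_asc[:, planted_idx] += sep * (trait.astype(float) - 0.5)
        asc_values = np.exp(log_asc)
        thresholds[planted_idx] = np.exp(mu[planted_idx])
    true_thresholds = {protein_ids[j]: float(thresholds[j]) for j in planted_idx}

    s = np.where(asc_values > thresholds[None, :], 1.0, -1.0)
    log_mult = cfg.effect_log_hr * (
        s[:, adverse_idx].sum(axis=1) - s[:, favorable_idx].sum(axis=1)
    )
    hazards = (math.log(2.0) / cfg.baseline_median_rfs_months) * np.exp(log_mult)

    T = r_surv.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        c_max = _uniform_censor_max(hazards, cfg.censoring_rate)
        C = r_cens.uniform(0.0, c_max, cfg.n_patients)
    else:
        C = np.full(cfg.n_patients, np.inf)
    rfs = np.minimum(T, C)
    event = T <= C

    # plasma samples: globally shifted baseline, no survival linkage
    n_plasma = cfg.n_oc_plasma + cfg.n_n_plasma
    plasma_ids = [f"OCP{i:03d}" for i in range(1, cfg.n_oc_plasma + 1)] + [
        f"NP{i:03d}" for i in range(1, cfg.n_n_plasma + 1)
    ]
    log_plasma = (
        mu[None, :]
        + cfg.plasma_log_shift
        + r_plasma.normal(0.0, cfg.abundance_log_sd, (n_plasma, cfg.n_proteins))
    )
    plasma_values = np.exp(log_plasma)

    values = pd.DataFrame(
        np.vstack([asc_values, plasma_values]),
        index=asc_ids + plasma_ids,
        columns=protein_ids,
    )
    classes = pd.Series(
        ["ascites"] * cfg.n_patients
        + ["oc_plasma"] * cfg.n_oc_plasma
        + ["n_plasma"] * cfg.n_n_plasma,
        index=values.index,
    )
    abundance = AbundanceMatrix(values, classes, platform="somascan-like")
    clinical = ClinicalTable(
        pd.DataFrame(
            {"rfs_months": rfs, "event": event}, index=pd.Index(patient_ids, name="patient_id")
        ),
        cutoff_months=cfg.rfs_cutoff_months,
    )
    cohort = CohortDataset(
        abundance, clinical, dict(zip(asc_ids, patient_ids))
    )
    truth = GroundTruth(
        adverse_ids=[protein_ids[j] for j in adverse_idx],
        favorable_ids=[protein_ids[j] for j in favorable_idx],
        true_thresholds=true_thresholds,
        patient_risk_class=pd.Series(
            np.where(log_mult > 0, "short", "long"), index=patient_ids
        ),
        cluster_labels=pd.Series(cluster, index=asc_ids),
        cluster_block_ids=[protein_ids[j] for j in block_idx],
        hazards=pd.Series(hazards, index=patient_ids),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# second platform


def generate_second_platform(
    m: AbundanceMatrix, rank_noise: float, seed: int
) -> AbundanceMatrix:
    """Noisy replicate of ``m`` on a second (antibody-like) platform.

    Each protein is passed through its own strictly increasing affine map on
    the log scale (different units and dynamic range per assay), plus
    additive Gaussian log-scale noise with standard deviation
    ``rank_noise`` times the protein's own log-scale spread.  With
    ``rank_noise = 0`` every marker's cross-platform Spearman rho is 1.
    """
    if rank_noise < 0:
        raise ValueError("rank_noise must be >= 0")
    rng = np.random.default_rng(seed)
    x = m.values.to_numpy(dtype=float)
    logx = np.log(np.maximum(x, 1e-12))
    sd = logx.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    slope = rng.uniform(0.6, 1.4, x.shape[1])
    intercept = rng.normal(0.0, 1.0, x.shape[1])
    noise = rng.normal(0.0, 1.0, x.shape) * (rank_noise * sd)[None, :]
    logy = intercept[None, :] + slope[None, :] * logx + noise
    values = pd.DataFrame(np.exp(logy), index=m.values.index, columns=m.values.columns)
    return AbundanceMatrix(values, m.sample_class, platform="pea-like")


def calibrate_rank_noise(
    target_rho: float,
    n_markers: int = 50,
    n_samples: int = 50,
    seed: int = 0,
    n_reps: int = 8,
    tol: float = 0.01,
    max_iter: int = 30,
):
    """Find the ``rank_noise`` whose median per-marker Spearman rho matches
    ``target_rho`` (Monte-Carlo bisection).

    Returns ``(rank_noise, achieved_median_rho)``.
    """
    if not 0 < target_rho < 1:
        raise ValueError("target_rho must be in (0,1)")
    from .concordance import spearman_per_marker

    rng = np.random.default_rng(seed)
    base_values = pd.DataFrame(
        np.exp(rng.normal(7.5, 1.0, (n_samples, n_markers))),
        index=[f"S{i:03d}" for i in range(n_samples)],
        columns=[f"M{i:03d}" for i in range(n_markers)],
    )
    base = AbundanceMatrix(
        base_values,
        pd.Series("ascites", index=base_values.index),
    )
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, n_reps)]

    def median_rho(noise):
        meds = []
        for s in rep_seeds:
            other = generate_second_platform(base, noise, seed=s)
            _, summary = spearman_per_marker(base, other)
            meds.append(summary["median_rho"])
        return float(np.mean(meds))

    lo, hi = 0.0, 1.0
    while median_rho(hi) > target_rho:
        hi *= 2.0
        if hi > 64:
            break
    achieved = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        achieved = median_rho(mid)
        if abs(achieved - target_rho) < tol:
            return mid, achieved
        if achieved > target_rho:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, median_rho(mid)


# ---------------------------------------------------------------------------
# EV fixtures


@dataclass
class EvSimulation:
    """EV-origin fixtures built on top of a cohort.

    ``cohort`` is a new dataset in which the designated EV-marker probes and
    the coupled high-abundance candidates are linear-plus-noise functions of
    a latent per-sample EV load; the input cohort is not modified.
    """

    ev_marker_ids: list
    ms_table: pd.DataFrame  # columns: protein_id, lfq
    cohort: CohortDataset
    coupled_candidate_ids: list = field(default_factory=list)


def generate_ev_tables(
    cohort: CohortDataset,
    n_ev_markers: int,
    seed: int,
    coupling: float = 1.0,
    noise_log_sd: float = 0.3,
    n_coupled: int = 10,
    n_ms_proteins: int = 300,
    n_overlap: int = 100,
) -> EvSimulation:
    """Designate EV markers, couple them (and high-abundance candidates) to a
    latent EV-load variable, and emit an MS-style (protein_id, LFQ) table
    overlapping the panel by ``n_overlap`` proteins.
    """
    if n_ev_markers < 1:
        raise ValueError("n_ev_markers must be >= 1")
    rng = np.random.default_rng(seed)
    abundance = cohort.abundance
    asc_mask = (abundance.sample_class == "ascites").to_numpy()
    proteins = list(abundance.values.columns)
    medians = abundance.values.loc[asc_mask].median(axis=0)

    order = medians.sort_values(ascending=False).index
    ev_ids = list(order[:n_ev_markers])
    candidates = [p for p in order[n_ev_markers:] if p not in ev_ids]
    coupled = candidates[:n_coupled]

    load = rng.normal(0.0, 1.0, int(asc_mask.sum()))
    values = abundance.values.copy()
    log_asc = np.log(np.maximum(values.loc[asc_mask, :].to_numpy(), 1e-12))
    col_index = {p: i for i, p in enumerate(proteins)}
    for p in ev_ids + list(coupled):
        j = col_index[p]
        base = np.log(max(float(medians[p]), 1e-12))
        log_asc[:, j] = base + coupling * load + rng.normal(0.0, noise_log_sd, len(load))
    values.loc[asc_mask, :] = np.exp(log_asc)
    new_abundance = AbundanceMatrix(values, abundance.sample_class, abundance.platform)
    new_cohort = CohortDataset(
        new_abundance, cohort.clinical, dict(cohort.sample_to_patient)
    )

    n_overlap = min(n_overlap, len(proteins), n_ms_proteins)
    overlap_ids = list(rng.choice(proteins, size=n_overlap, replace=False))
    extra = [f"MSONLY{i:04d}" for i in range(n_ms_proteins - n_overlap)]
    ms_ids = overlap_ids + extra
    # LFQ loosely tracks panel abundance for overlapping proteins
    lfq = []
    for p in ms_ids:
        if p in col_index:
            lfq.append(
                float(
                    np.exp(
                        0.8 * np.log(max(float(medians[p]), 1e-12))
                        + rng.normal(0.0, 0.5)
                        + 5.0
                    )
                )
            )
        else:
            lfq.append(float(np.exp(rng.normal(11.0, 1.5))))
    ms_table = pd.DataFrame({"protein_id": ms_ids, "lfq": lfq})
    return EvSimulation(
        ev_marker_ids=ev_ids,
        ms_table=ms_table,
        cohort=new_cohort,
        coupled_candidate_ids=list(coupled),
    )
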