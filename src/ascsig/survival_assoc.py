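"""Per-protein survival association by best-fit-quantile dichotomization.

For each protein, patients are split at each quantile of a scanned grid
(default {0.3, 0.4, 0.5, 0.6, 0.7}); the split minimizing the logrank
p-value is the protein's *best-fit* dichotomization, reported with its
threshold, nominal logrank p, Cox hazard ratio (high vs low) and per-group
Kaplan-Meier median RFS.  Because the best-fit p is the minimum of several
dependent tests it is anti-conservative; no multiplicity correction is
applied (nominal p-values), matching the analysis convention this package
reproduces.  The grid-scan inflation is quantified by the null-calibration
tests rather than corrected.

Also here: trichotomization by three markers' thresholds, group-wise
differential abundance (equal-variance t-test + Benjamini-Hochberg, fold
change as a plain ratio of arithmetic means), and a minimal 2-cluster
assignment utility for ascites samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import SurvivalScan, km_median, logrank_p_value, cox_binary_hr
from .core_data import CohortDataset, AbundanceMatrix

__all__ = [
    "DEFAULT_QUANTILE_GRID",
    "DichotomizationResult",
    "logrank_p",
    "cox_hr",
    "best_fit_dichotomize",
    "associate_all",
    "trichotomize",
    "differential_abundance",
    "cluster_ascites",
]

DEFAULT_QUANTILE_GRID = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class DichotomizationResult:
    """Best-fit split of one protein: quantile, threshold, logrank p, HR and
    group median RFS (months; ``inf`` when not reached)."""

    protein_id: str
    best_quantile: float
    threshold_value: float
    logrank_p: float
    hr: float
    median_rfs_high: float
    median_rfs_low: float
    n: int
    converged: bool = True


def logrank_p(group_a, group_b):
    """Nominal two-group logrank p-value.

    Each group is a ``(times, events)`` pair.  Undefined statistics (e.g.
    zero events) yield 1.0 with a warning.
    """
    (ta, ea), (tb, eb) = group_a, group_b
    return logrank_p_value(ta, ea, tb, eb)


def cox_hr(times, events, group_indicator):
    """Univariate proportional-hazards HR for indicator=1 (high) vs 0 (low).

    Complete separation is reported as an ``inf``/``0.0`` sentinel with
    ``converged=False`` on the returned result.
    """
    return cox_binary_hr(times, events, group_indicator)


def _select_best(p_values, grid):
    """Index of the minimal p; ties resolved toward the most balanced split
    (q closest to 0.5), then the smaller q."""
    p_values = np.asarray(p_values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    best_p = p_values.min()
    tied = np.flatnonzero(np.isclose(p_values, best_p, rtol=0, atol=0))
    if len(tied) == 1:
        return int(tied[0])
    dist = np.abs(grid[tied] - 0.5)
    tied = tied[dist == dist.min()]
    return int(tied[grid[tied].argmin()])


def best_fit_dichotomize(
    values, times, events, grid=DEFAULT_QUANTILE_GRID, protein_id="protein", scan=None
) -> DichotomizationResult:
    """Scan the quantile grid and return the split minimizing the logrank p.

    ``high`` means strictly greater than the quantile threshold; ties at
    the threshold go to the low group.
    """
    values = np.asarray(values, dtype=float)
    grid = tuple(grid)
    if not all(0 < q < 1 for q in grid):
        raise ValueError("grid quantiles must lie in (0,1)")
    if len(np.unique(values)) < 2:
        raise ValueError(f"degenerate dichotomization: constant values for {protein_id}")
    if scan is None:
        scan = SurvivalScan(times, events)
    thresholds = np.quantile(values, grid)
    G = values[:, None] > thresholds[None, :]
    p, _, _ = scan.logrank(G)
    # splits with an empty group are undefined; p already 1.0 there
    best = _select_best(p, grid)
    thr = float(thresholds[best])
    high = values > thr
    if high.all() or not high.any():
        raise ValueError(
            f"degenerate dichotomization: empty group at every grid point for {protein_id}"
        )
    hr_res = cox_binary_hr(times, events, high)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    return DichotomizationResult(
        protein_id=protein_id,
        best_quantile=float(grid[best]),
        threshold_value=thr,
        logrank_p=float(p[best]),
        hr=hr_res.hr,
        median_rfs_high=km_median(t[high], e[high]),
        median_rfs_low=km_median(t[~high], e[~high]),
        n=len(values),
        converged=hr_res.converged,
    )


def associate_all(
    cohort: CohortDataset, grid=DEFAULT_QUANTILE_GRID, alpha=0.05
) -> pd.DataFrame:
    """Best-fit dichotomization of every protein against patient RFS.

    Returns an association table (one row per protein) with columns
    ``q, threshold, p, hr, median_rfs_high, median_rfs_low, n, significant,
    direction``; ``direction`` is ``adverse`` (HR>1) or ``favorable``
    (HR<1).  Degenerate (constant) proteins are skipped with a warning.
    """
    grid = tuple(grid)
    pv = cohort.patient_values()
    times, events = cohort.survival_arrays(pv.index)
    scan = SurvivalScan(times, events)
    X = pv.to_numpy(dtype=float)
    n_pat, n_prot = X.shape

    degenerate = np.array([len(np.unique(X[:, j])) < 2 for j in range(n_prot)])
    if degenerate.any():
        warnings.warn(
            f"skipping {int(degenerate.sum())} constant protein(s): "
            f"{list(pv.columns[degenerate])[:5]}"
        )
    cols = np.flatnonzero(~degenerate)
    thresholds = np.quantile(X[:, cols], grid, axis=0)  # (g, m)
    n_grid = len(grid)
    # one batched logrank over all protein x quantile splits
    G = X[:, cols][:, :, None] > thresholds.T[None, :, :]  # (n, m, g)
    G = G.reshape(n_pat, -1)
    p_all, ome_all, _ = scan.logrank(G)
    p_all = p_all.reshape(len(cols), n_grid)

    rows = []
    best_high = np.empty((n_pat, len(cols)), dtype=bool)
    best_idx = np.empty(len(cols), dtype=int)
    for i in range(len(cols)):
        best = _select_best(p_all[i], grid)
        best_idx[i] = best
        best_high[:, i] = X[:, cols[i]] > thresholds[best, i]
    hr, converged = scan.cox_binary(best_high)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    for i, j in enumerate(cols):
        high = best_high[:, i]
        if high.all() or not high.any():
            warnings.warn(f"skipping {pv.columns[j]!r}: empty group at every split")
            continue
        rows.append(
            {
                "protein": pv.columns[j],
                "q": float(grid[best_idx[i]]),
                "threshold": float(thresholds[best_idx[i], i]),
                "p": float(p_all[i, best_idx[i]]),
                "hr": float(hr[i]),
                "median_rfs_high": km_median(t[high], e[high]),
                "median_rfs_low": km_median(t[~high], e[~high]),
                "n": n_pat,
                "converged": bool(converged[i]),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=[
                "protein", "q", "threshold", "p", "hr", "median_rfs_high",
                "median_rfs_low", "n", "converged", "significant", "direction",
            ]
        ).set_index("protein")
    table["significant"] = table["p"] < alpha
    table["direction"] = np.where(table["hr"] > 1.0, "adverse", "favorable")
    return table.set_index("protein")


def trichotomize(cohort: CohortDataset, proteins, thresholds):
    """Partition patients into all_high / all_low / mixed by three markers.

    ``thresholds`` maps each of the three protein ids to its best-fit
    threshold.  Returns a dict with per-group patient lists, group sizes and
    the logrank p between the all_high and all_low groups (``None`` with a
    flag if either group has < 2 patients).
    """
    proteins = list(proteins)
    if len(proteins) != 3:
        raise ValueError("trichotomization needs exactly 3 proteins")
    missing = [p for p in proteins if p not in thresholds]
    if missing:
        raise ValueError(f"no threshold for {missing}")
    pv = cohort.patient_values()
    times, events = cohort.survival_arrays(pv.index)
    above = np.column_stack(
        [pv[p].to_numpy(dtype=float) > float(thresholds[p]) for p in proteins]
    )
    all_high = above.all(axis=1)
    all_low = (~above).all(axis=1)
    mixed = ~(all_high | all_low)
    groups = {
        "all_high": list(pv.index[all_high]),
        "all_low": list(pv.index[all_low]),
        "mixed": list(pv.index[mixed]),
    }
    result = {
        "groups": groups,
        "sizes": {k: len(v) for k, v in groups.items()},
        "logrank_p": None,
        "p_defined": False,
    }
    if all_high.sum() >= 2 and all_low.sum() >= 2:
        result["logrank_p"] = logrank_p(
            (times[all_high], events[all_high]), (times[all_low], events[all_low])
        )
        result["p_defined"] = True
    else:
        warnings.warn("trichotomization group with <2 patients; p undefined")
    return result


def differential_abundance(
    m: AbundanceMatrix,
    group_a: str,
    group_b: str,
    fc_min: float = 5.0,
    alpha: float = 0.05,
    filter: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sided equal-variance t-test between two sample
    classes with Benjamini-Hochberg adjustment.

    Fold change is the plain ratio of arithmetic means, group_a / group_b
    (``inf`` sentinel when the denominator mean is zero).  With
    ``filter=True`` only rows with adjusted p < ``alpha`` and fold change
    strictly greater than ``fc_min`` are returned.
    """
    a = m.values[(m.sample_class == group_a).to_numpy()]
    b = m.values[(m.sample_class == group_b).to_numpy()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = stats.ttest_ind(a.to_numpy(), b.to_numpy(), equal_var=True)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    mean_a = a.mean(axis=0).to_numpy()
    mean_b = b.mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.inf)
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=pd.Index(m.values.columns, name="protein"),
    )
    table["retained"] = (table["p_adjusted"] < alpha) & (table["fold_change"] > fc_min)
    table = table.sort_values("p_adjusted")
    return table[table["retained"]] if filter else table


def cluster_ascites(m: AbundanceMatrix, k: int = 2) -> pd.Series:
    """Agglomerative (Ward) clustering of ascites samples on
    log-transformed, per-protein standardized values; returns k labels."""
    from sklearn.cluster import AgglomerativeClustering

    asc = m.values[(m.sample_class == "ascites").to_numpy()]
    if k > len(asc):
        raise ValueError(f"k={k} exceeds {len(asc)} ascites samples")
    if k == 1:
        return pd.Series(0, index=asc.index)
    logx = np.log(np.maximum(asc.to_numpy(dtype=float), 1e-12))
    sd = logx.std(axis=0, ddof=0)
    z = (logx - logx.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)
    return pd.Series(labels, index=asc.index)
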