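"""Cross-platform agreement and EV-origin correlation analyses.

Per-marker Spearman rank correlation between two abundance matrices
measured on the same samples (aptamer-like vs antibody-like platforms),
binned as in the dual-platform comparison (rho > 0.75; 0.75 >= rho > 0.5;
0.5 >= rho > 0; rho < 0; rho = 0 falls in the 0-to-0.5 bin).  Also:
correlation of extracellular-vesicle (EV) markers with high-abundance
RFS-associated signals in ascites, and the intersection of an MS-derived
EV proteome with the affinity panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AbundanceMatrix

__all__ = [
    "ConcordanceResult",
    "bin_rho",
    "spearman_per_marker",
    "ev_correlation",
    "intersect_ev_proteome",
]

BINS = ("gt_0.75", "0.5_to_0.75", "0_to_0.5", "negative")


@dataclass
class ConcordanceResult:
    marker_id: str
    rho: float
    n_samples: int
    bin: str


def bin_rho(rho: float) -> str:
    """Concordance bin of a Spearman rho (rho = 0 -> ``0_to_0.5``)."""
    if rho > 0.75:
        return "gt_0.75"
    if rho > 0.5:
        return "0.5_to_0.75"
    if rho >= 0.0:
        return "0_to_0.5"
    return "negative"


def spearman_per_marker(a: AbundanceMatrix, b: AbundanceMatrix, shared_markers=None):
    """Per-marker Spearman rho across matched samples, with summary.

    Both matrices must cover the same sample set (any order); markers
    constant on either platform are excluded with a warning.  Returns
    ``(results, summary)`` where summary holds the median rho, the percent
    positive/negative, per-bin counts and the sorted rho values (the
    cumulative distribution).
    """
    if set(a.values.index) != set(b.values.index):
        raise ValueError("platforms must cover the same sample set")
    if len(a.values) < 3:
        raise ValueError("need at least 3 matched samples")
    if shared_markers is None:
        shared_markers = [m for m in a.values.columns if m in set(b.values.columns)]
    bv = b.values.loc[a.values.index]
    results = []
    dropped = []
    for marker in shared_markers:
        x = a.values[marker].to_numpy(dtype=float)
        y = bv[marker].to_numpy(dtype=float)
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            dropped.append(marker)
            continue
        rho = stats.spearmanr(x, y).statistic
        results.append(
            ConcordanceResult(
                marker_id=marker, rho=float(rho), n_samples=len(x), bin=bin_rho(rho)
            )
        )
    if dropped:
        warnings.warn(f"excluded constant marker(s): {dropped[:5]}")
    rhos = np.array([r.rho for r in results])
    summary = {
        "n_markers": len(results),
        "median_rho": float(np.median(rhos)) if len(rhos) else np.nan,
        "pct_positive": float(100.0 * (rhos > 0).mean()) if len(rhos) else np.nan,
        "pct_negative": float(100.0 * (rhos < 0).mean()) if len(rhos) else np.nan,
        "bin_counts": {bn: int(sum(r.bin == bn for r in results)) for bn in BINS},
        "sorted_rho": np.sort(rhos),
    }
    return results, summary


def ev_correlation(
    m: AbundanceMatrix,
    ev_markers,
    candidates,
    min_median_units: float = 10_000.0,
) -> pd.DataFrame:
    """Spearman rho of each EV marker against each high-abundance candidate.

    Computed on ascites samples only; candidates are restricted to those
    with median abundance strictly greater than ``min_median_units``.
    Returns a heatmap-ready table (rows: EV markers, columns: retained
    candidates); empty with a warning when no candidate passes the filter.
    """
    asc = m.values[(m.sample_class == "ascites").to_numpy()]
    ev_markers = [p for p in ev_markers if p in asc.columns]
    medians = asc.median(axis=0)
    retained = [
        c
        for c in candidates
        if c in asc.columns and float(medians[c]) > min_median_units
    ]
    if not retained:
        warnings.warn("no candidate passes the median-abundance filter")
        return pd.DataFrame(index=pd.Index(ev_markers, name="ev_marker"))
    out = np.empty((len(ev_markers), len(retained)))
    for i, ev in enumerate(ev_markers):
        x = asc[ev].to_numpy(dtype=float)
        for j, c in enumerate(retained):
            out[i, j] = stats.spearmanr(x, asc[c].to_numpy(dtype=float)).statistic
    return pd.DataFrame(
        out, index=pd.Index(ev_markers, name="ev_marker"), columns=retained
    )


def intersect_ev_proteome(ms_table: pd.DataFrame, panel: AbundanceMatrix) -> pd.DataFrame:
    """Inner join of an MS (protein_id, LFQ) table with the affinity panel.

    Returns one row per overlapping protein with its median LFQ and its
    median panel units over ascites samples (scatter export); empty when
    the sets are disjoint.  Identifiers are matched by exact symbol.
    """
    if not {"protein_id", "lfq"}.issubset(ms_table.columns):
        raise ValueError("ms_table must have columns protein_id, lfq")
    asc = panel.values[(panel.sample_class == "ascites").to_numpy()]
    medians = asc.median(axis=0)
    ms_med = ms_table.groupby("protein_id")["lfq"].median()
    overlap = [p for p in ms_med.index if p in set(asc.columns)]
    return pd.DataFrame(
        {
            "protein_id": overlap,
            "median_lfq": [float(ms_med[p]) for p in overlap],
            "median_panel_units": [float(medians[p]) for p in overlap],
        }
    )
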